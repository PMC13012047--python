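"""Cruise observations, selection filters, model sampling, and the cost.

The model is assessed against discrete-sample transects: per transect the
RMSE between predicted and observed [CH4] is computed, and the overall
misfit is the weighted sum

    cost = Σ_i RMSE_i * w_i,      w_i = n_i / Σ_j n_j,

with n_i the number of datapoints in transect i.  The weights are
normalized to sum to one so that costs are comparable across data subsets
(as needed for bootstrap resampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .forcing import AtmosphereHistory, ForcingFields, saturation, solubility
from .model import ModelState

if TYPE_CHECKING:  # pragma: no cover
    from .production import BioFields
    from .world import Grid

__all__ = [
    "CruiseTransect",
    "CostBreakdown",
    "select_cruises",
    "sample_model",
    "disequilibrium",
    "regional_disequilibrium",
    "cost",
    "OMZ_O2_THRESHOLD",
    "MIN_PROFILE_DEPTH",
]

#: O2 concentration (µM) below which a water column counts as an OMZ
OMZ_O2_THRESHOLD = 5.0

#: minimum profile depth (m) for a transect to constrain subsurface supply
MIN_PROFILE_DEPTH = 500.0


@dataclass
class CruiseTransect:
    """One cruise's discrete samples: positions, depths, [CH4] and its sd."""

    cruise_id: str
    year: float
    lat: np.ndarray
    lon: np.ndarray
    depth: np.ndarray
    ch4: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        n = len(self.lat)
        for name in ("lon", "depth", "ch4", "sd"):
            if len(getattr(self, name)) != n:
                raise ValueError("sample arrays must have equal length")
        if n < 1:
            raise ValueError("a transect needs at least one sample")
        if np.any(self.depth < 0) or np.any(self.ch4 < 0):
            raise ValueError("depths and concentrations must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.lat)

    @property
    def max_depth(self) -> float:
        return float(np.max(self.depth))

    def subset(self, idx: np.ndarray) -> "CruiseTransect":
        return CruiseTransect(
            cruise_id=self.cruise_id, year=self.year,
            lat=self.lat[idx], lon=self.lon[idx], depth=self.depth[idx],
            ch4=self.ch4[idx], sd=self.sd[idx],
        )


@dataclass
class CostBreakdown:
    """Per-transect RMSE (nM), normalized weights, and the total cost."""

    cruise_ids: list
    rmse: np.ndarray
    weights: np.ndarray
    total: float

    def to_csv(self, path) -> None:
        """Per-transect diagnostics table (cruise_id, rmse_nM, weight)."""
        import pandas as pd

        pd.DataFrame({
            "cruise_id": self.cruise_ids,
            "rmse_nM": self.rmse,
            "weight": self.weights,
        }).to_csv(path, index=False)


def select_cruises(cruises, bio: "BioFields", grid: "Grid"):
    """Apply the data-selection rules.

    Retains transects that (i) resolve the water column to at least 500 m
    (surface-only, equilibrator-style records are thereby dropped), and
    (ii) never cross a water column containing O2 below 5 µM (oxygen
    minimum zones host methane cycling outside this model's scope).
    """
    o2_min_col = bio.o2.min(axis=0)  # (nlat, nlon)
    kept = []
    for c in cruises:
        if c.max_depth < MIN_PROFILE_DEPTH:
            continue
        crosses_omz = False
        for la, lo in zip(c.lat, c.lon):
            j, i = grid.column_index(la, lo)
            if o2_min_col[j, i] < OMZ_O2_THRESHOLD:
                crosses_omz = True
                break
        if not crosses_omz:
            kept.append(c)
    if not kept:
        warnings.warn("no cruises survived the selection filters", stacklevel=2)
    return kept


def _interpolator(state: ModelState, grid: "Grid") -> RegularGridInterpolator:
    # pad the longitude axis for periodic wraparound
    field = state.c.reshape(grid.shape)
    lon_pad = np.concatenate([grid.lon, [grid.lon[0] + 360.0]])
    field_pad = np.concatenate([field, field[:, :, :1]], axis=2)
    return RegularGridInterpolator(
        (grid.depth, grid.lat, lon_pad), field_pad,
        bounds_error=False, fill_value=None,
    )


def _clamped_points(transect: CruiseTransect, grid: "Grid") -> tuple[np.ndarray, np.ndarray]:
    """Sample coordinates clamped into the grid's center range.

    Samples below the deepest cell center (or poleward of the last row)
    are clamped to the nearest wet cell rather than dropped, keeping n_i
    stable; the returned flag marks clamped samples.
    """
    lon = transect.lon % 360.0
    # map into the padded periodic range [lon[0], lon[0]+360)
    lon = np.where(lon < grid.lon[0], lon + 360.0, lon)
    depth = np.clip(transect.depth, grid.depth[0], grid.depth[-1])
    lat = np.clip(transect.lat, grid.lat[0], grid.lat[-1])
    flagged = (depth != transect.depth) | (lat != transect.lat)
    return np.column_stack([depth, lat, lon]), flagged


def sample_model(states: list[ModelState], transect: CruiseTransect, grid: "Grid") -> np.ndarray:
    """Predicted [CH4] at each sample of a transect.

    Trilinear interpolation in (depth, lat, lon) of the model state at the
    cruise year, linearly interpolated in time between the bracketing
    output snapshots (decadal before 1991, annual after).
    """
    years = np.array([s.year for s in states])
    t = transect.year
    if t < years.min() - 1e-9 or t > years.max() + 1e-9:
        raise ValueError(
            f"cruise year {t} outside the simulated span [{years.min()}, {years.max()}]"
        )
    pts, _ = _clamped_points(transect, grid)
    i_after = int(np.searchsorted(years, t, side="left"))
    i_after = min(i_after, len(years) - 1)
    if abs(years[i_after] - t) < 1e-9 or i_after == 0:
        return np.asarray(_interpolator(states[i_after], grid)(pts))
    i_before = i_after - 1
    v0 = _interpolator(states[i_before], grid)(pts)
    v1 = _interpolator(states[i_after], grid)(pts)
    f = (t - years[i_before]) / (years[i_after] - years[i_before])
    return np.asarray((1.0 - f) * v0 + f * v1)


def disequilibrium(
    transect: CruiseTransect,
    forcing: ForcingFields,
    atm: AtmosphereHistory,
    grid: "Grid",
    values: np.ndarray | None = None,
    max_depth: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔCH4 = [CH4] - S_CH4 for the surface samples of a transect.

    Returns (delta, surface_mask); delta is computed only for samples in
    the top ``max_depth`` m, using the local forcing (SST, salinity,
    pressure of the nearest column) and the atmosphere at the cruise year.
    Positive delta = supersaturation.  ``values`` substitutes model
    predictions for the observed concentrations.
    """
    vals = transect.ch4 if values is None else np.asarray(values)
    surface = transect.depth <= max_depth
    x = atm.value(transect.year)
    delta = np.full(transect.n_samples, np.nan)
    for idx in np.nonzero(surface)[0]:
        j, i = grid.column_index(transect.lat[idx], transect.lon[idx])
        k_sol = solubility(forcing.sst[j, i], forcing.salinity[j, i])
        s = saturation(x, forcing.pressure[j, i], k_sol)
        delta[idx] = vals[idx] - s
    return delta, surface


def regional_disequilibrium(
    cruises,
    forcing: ForcingFields,
    atm: AtmosphereHistory,
    grid: "Grid",
    predictions: dict | None = None,
) -> dict:
    """Mean surface ΔCH4 by region label: region -> (mean_delta_nM, n).

    ``predictions`` maps cruise_id -> model values to aggregate predicted
    instead of observed disequilibrium.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for c in cruises:
        vals = None if predictions is None else predictions[c.cruise_id]
        delta, surface = disequilibrium(c, forcing, atm, grid, values=vals)
        for idx in np.nonzero(surface)[0]:
            j, i = grid.column_index(c.lat[idx], c.lon[idx])
            region = str(grid.region[j, i])
            sums[region] = sums.get(region, 0.0) + float(delta[idx])
            counts[region] = counts.get(region, 0) + 1
    return {r: (sums[r] / counts[r], counts[r]) for r in sums}


def regional_summary_to_json(summary: dict, path) -> None:
    """Write a regional_disequilibrium result as region -> {mean_nM, n}."""
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps(
        {r: {"mean_nM": v[0], "n": v[1]} for r, v in summary.items()}, indent=2
    ))


def cost(predictions: list[np.ndarray], transects: list[CruiseTransect]) -> CostBreakdown:
    """Eq.-style weighted cost: Σ RMSE_i * n_i / Σ n_j over the transects.

    Empty transects are excluded with a warning.  Invariant under transect
    ordering and under splitting a transect into parts with the same
    samples.
    """
    if len(predictions) != len(transects):
        raise ValueError("predictions must align 1:1 with transects")
    ids, rmses, ns = [], [], []
    for pred, obs in zip(predictions, transects):
        pred = np.asarray(pred)
        if pred.shape != obs.ch4.shape:
            raise ValueError(f"prediction shape mismatch for {obs.cruise_id}")
        if obs.n_samples == 0:
            warnings.warn(f"empty transect {obs.cruise_id} excluded from cost", stacklevel=2)
            continue
        ids.append(obs.cruise_id)
        rmses.append(float(np.sqrt(np.mean((pred - obs.ch4) ** 2))))
        ns.append(obs.n_samples)
    ns_arr = np.asarray(ns, dtype=float)
    weights = ns_arr / ns_arr.sum()
    rmse = np.asarray(rmses)
    return CostBreakdown(
        cruise_ids=ids, rmse=rmse, weights=weights, total=float((rmse * weights).sum())
    )
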