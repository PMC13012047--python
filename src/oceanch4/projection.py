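"""Future oxic CH4 production under prescribed phosphate depletion.

Climate-model simulations of high-emission scenarios predict that
stratification and high-latitude nutrient trapping deplete low-latitude
surface phosphate through 2300.  The projection imposes such a scenario
trajectory on the observed (here: synthetic) PO4 field in one of two
modes — the scenario's absolute change added (floored at zero) or its
relative change multiplied — and re-evaluates the calibrated
PO4-inhibited production parameterization each year.  Because that
parameterization does not depend on the CH4 concentration itself, the
projected quantity is the integrated production rate; re-integrating the
full tracer field is available for inspection but does not change it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .production import ProductionConfig, jprod_po4
from .units import umol_to_tg

__all__ = ["ScenarioPO4", "synthetic_scenario", "perturb_po4", "project_production"]


@dataclass
class ScenarioPO4:
    """A scenario PO4 trajectory: fields (nyear, nz, nlat, nlon) at the
    tabulated years, the 2005-style baseline year among them, and the
    default application mode ('absolute' or 'relative')."""

    baseline_year: float
    years: np.ndarray
    fields: np.ndarray
    mode: str = "absolute"

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        self.fields = np.asarray(self.fields, dtype=float)
        if self.baseline_year not in self.years:
            raise ValueError("baseline year must be among the scenario years")
        if np.any(self.fields < 0):
            raise ValueError("scenario PO4 fields must be nonnegative")
        if self.mode not in ("absolute", "relative"):
            raise ValueError("mode must be 'absolute' or 'relative'")

    @property
    def baseline(self) -> np.ndarray:
        return self.fields[int(np.argwhere(self.years == self.baseline_year)[0, 0])]

    def field_at(self, year: float) -> np.ndarray:
        """Scenario field linearly interpolated in time (clamped at ends)."""
        if year <= self.years[0]:
            return self.fields[0]
        if year >= self.years[-1]:
            return self.fields[-1]
        i = int(np.searchsorted(self.years, year)) - 1
        f = (year - self.years[i]) / (self.years[i + 1] - self.years[i])
        return (1 - f) * self.fields[i] + f * self.fields[i + 1]

    def to_netcdf(self, grid, path) -> None:
        xr.Dataset(
            {"po4": (("year", "depth", "lat", "lon"), self.fields)},
            coords={"year": self.years, "depth": grid.depth,
                    "lat": grid.lat, "lon": grid.lon},
            attrs={"baseline_year": self.baseline_year, "mode": self.mode},
        ).to_netcdf(path)


def synthetic_scenario(
    world,
    decline_frac: float = 0.25,
    year0: float = 2005.0,
    year1: float = 2300.0,
    lat_extent: float = 45.0,
    step: float = 5.0,
    mode: str = "absolute",
) -> ScenarioPO4:
    """Smooth low-latitude surface-PO4 decline, ~25% from 2005 to 2300.

    Emulates the trend climate models project under sustained warming: a
    smoothstep decline of ``decline_frac`` applied to the upper-ocean PO4
    equatorward of ``lat_extent``, tapering to zero at high latitudes and
    below ~500 m (deep nutrients are unaffected on this horizon).

    The scenario's own baseline field is a deliberately biased rendering
    of the world's PO4 (compressed toward 0.25 µM), the way a free-running
    climate model's nutrient field differs from observations — which is
    why applying its absolute and relative changes to the observed field
    give different trajectories.
    """
    grid = world.grid
    years = np.arange(year0, year1 + 0.5 * step, step)
    tau = np.clip((years - year0) / (year1 - year0), 0.0, 1.0)
    smooth = tau * tau * (3.0 - 2.0 * tau)
    lat_shape = np.exp(-((grid.lat[None, :, None] / lat_extent) ** 4))
    z_shape = np.exp(-(grid.depth[:, None, None] / 500.0) ** 2)
    pattern = lat_shape * z_shape  # (nz, nlat, nlon) via broadcast
    base = 0.75 * world.bio.po4 + 0.0625
    fields = np.stack([
        np.clip(base * (1.0 - decline_frac * s * pattern), 0.0, None) for s in smooth
    ])
    return ScenarioPO4(baseline_year=year0, years=years, fields=fields, mode=mode)


def perturb_po4(
    p_obs: np.ndarray,
    scenario: ScenarioPO4,
    year: float,
    mode: str | None = None,
    return_flags: bool = False,
):
    """Scenario-adjusted PO4 for one year.

    absolute: max(0, P_obs + P_scen(t) - P_scen(baseline));
    relative: P_obs * P_scen(t) / P_scen(baseline), with zero-baseline
    cells left at P_obs and flagged (the ratio is undefined there).
    At the baseline year both modes return P_obs exactly.
    """
    mode = mode or scenario.mode
    if year < scenario.baseline_year:
        raise ValueError("projection year precedes the scenario baseline")
    p_obs = np.asarray(p_obs, dtype=float)
    p_t = scenario.field_at(year)
    p_0 = scenario.baseline
    flags = np.zeros(p_obs.shape, dtype=bool)
    # difference/ratio taken first so the baseline-year identity is exact
    if mode == "absolute":
        out = np.maximum(0.0, p_obs + (p_t - p_0))
    elif mode == "relative":
        flags = p_0 == 0.0
        ratio = np.where(flags, 1.0, p_t / np.where(flags, 1.0, p_0))
        out = p_obs * ratio
    else:
        raise ValueError("mode must be 'absolute' or 'relative'")
    return (out, flags) if return_flags else out


def _integrated_production_tg(world, params: dict, po4_field: np.ndarray) -> float:
    bio = world.bio
    cfg = ProductionConfig("po4", {k: params[k] for k in ("a_0", "p_crit", "w")})
    fields = type(bio)(
        po4=po4_field, npp=bio.npp, f_m=bio.f_m, f_n=bio.f_n, f_p=bio.f_p,
        b_z=bio.b_z, temperature=bio.temperature, o2=bio.o2,
        s_lab=bio.s_lab, s_semi=bio.s_semi, dms=bio.dms,
        z_ml=bio.z_ml, z_eu=bio.z_eu, z_dvm=bio.z_dvm,
    )
    jp = jprod_po4(fields, cfg, world.grid)
    return umol_to_tg(float((jp * world.grid.volume).sum()))


def project_production(
    world,
    params,
    scenario: ScenarioPO4,
    years=None,
    modes=("absolute", "relative"),
) -> pd.DataFrame:
    """Global integrated oxic CH4 production (Tg y⁻¹) per year and mode.

    ``params`` is either one calibrated parameter dict (a_0, p_crit, w,
    possibly with the oxidation pair) or a bootstrap ensemble / list of
    such dicts, in which case the envelope statistics (mean, sd, min,
    max) per year come from the member trajectories.
    """
    if years is None:
        years = scenario.years
    years = np.asarray(years, dtype=float)
    if hasattr(params, "members"):  # BootstrapEnsemble
        param_sets = [m.params for m in params.members]
    elif isinstance(params, dict):
        param_sets = [params]
    else:
        param_sets = list(params)

    rows = []
    for mode in modes:
        for year in years:
            po4 = perturb_po4(world.bio.po4, scenario, year, mode=mode)
            vals = np.array([
                _integrated_production_tg(world, p, po4) for p in param_sets
            ])
            rows.append(
                {
                    "year": year,
                    "mode": mode,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    "min": vals.min(),
                    "max": vals.max(),
                }
            )
    return pd.DataFrame(rows)
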