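"""Basin-integrated production, sea–air exchange, and the fate of
biologically produced methane.

Three fates are open to methane produced in oxygenated surface waters:
emission to the atmosphere, oxidation within the mixed layer, or export
to the ocean interior (followed by oxidation at depth).  Because the
mixed layer equilibrates with the atmosphere in days–weeks while the
oxidation timescale is of order a century, and because phosphate
scarcity confines production to stratified subtropical gyres where
export is a sluggish downwelling, emission dominates.

Fate attribution uses the component decomposition (the bio share of the
local concentration), pro-rata for the threshold oxidation: exact
additivity of the components makes the attribution well-defined.  The
"mixed layer" for fate accounting is the model's surface layer — the
layer on which the gas-exchange operator acts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import GasExchangeOperator
from .model import ModelState, OxidationParams, oxidation_rate
from .units import umol_to_tg
from .world import BASINS, ideal_age

__all__ = ["BasinBudget", "basin_budget", "fate_timescales"]


@dataclass
class BasinBudget:
    """Per-basin and global budget terms, Tg CH4 y⁻¹.

    ``table`` rows: production, net sea–air flux (positive = outgassing),
    bio emission, bio mixed-layer oxidation, bio export to the interior
    (transport route, storage-corrected).  ``closure`` is the relative
    budget residual |production - (emission + ML-oxidation + export)| /
    production per basin (global included).
    """

    table: pd.DataFrame
    closure: pd.Series
    window_years: tuple

    def basin(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps({
            "window_years": list(self.window_years),
            "budget_tg_per_yr": {b: dict(r) for b, r in self.table.iterrows()},
            "closure": dict(self.closure),
        }, indent=2))


def _window_states(states: list[ModelState], window: float) -> list[ModelState]:
    t_end = states[-1].year
    return [s for s in states if s.year >= t_end - window]


def basin_budget(
    full_states: list[ModelState],
    nobio_states: list[ModelState],
    world,
    gx: GasExchangeOperator,
    ox: OxidationParams,
    jprod: np.ndarray,
    window: float = 10.0,
) -> BasinBudget:
    """Integrate the budget terms per basin over the trailing window.

    Requires the full and production-disabled runs on identical output
    years (the component subtraction is taken per snapshot and averaged
    over the last ``window`` years).  The bio export is computed
    independently of the other terms — as the net transport of the bio
    component out of the surface layer, plus its storage change, plus
    any production injected below the surface layer — so the closure
    residual is a genuine conservation check, not an identity.
    """
    grid = world.grid
    full_w = _window_states(full_states, window)
    nobio_w = _window_states(nobio_states, window)
    if [s.year for s in full_w] != [s.year for s in nobio_w]:
        raise ValueError("full and J_prod=0 runs must share output years")
    if len(full_w) < 2:
        raise ValueError("need at least two snapshots in the averaging window")

    vol = grid.volume
    surf_vol = vol[0]
    qgx = gx.qgx_surface
    jp = np.asarray(jprod).reshape(grid.shape)
    basins = list(BASINS)
    masks = {b: (grid.basin == b) for b in basins}

    prod_col = (jp * vol).sum(axis=0)            # µmol/y per column, all depths
    prod_sub_col = (jp[1:] * vol[1:]).sum(axis=0)  # injected below the surface layer

    def accumulate(full: ModelState, nobio: ModelState, year: float):
        c_full = full.c.reshape(grid.shape)
        c_nobio = nobio.c.reshape(grid.shape)
        bio = c_full - c_nobio
        x = world.atmosphere.value(year)
        s_surf = gx.saturation_surface(x)
        net_flux = qgx * (c_full[0] - s_surf) * surf_vol          # µmol/y, + out
        bio_emis = qgx * bio[0] * surf_vol
        bio_ox = (oxidation_rate(c_full[0], ox) - oxidation_rate(c_nobio[0], ox)) * surf_vol
        # transport of the bio component out of the surface layer
        tend = (world.transport.matrix @ bio.ravel()).reshape(grid.shape)[0]
        bio_export_transport = -(tend * surf_vol)
        return net_flux, bio_emis, bio_ox, bio_export_transport, bio[0] * surf_vol

    terms = [accumulate(f, n, f.year) for f, n in zip(full_w, nobio_w)]
    net_flux = np.mean([t[0] for t in terms], axis=0)
    bio_emis = np.mean([t[1] for t in terms], axis=0)
    bio_ox = np.mean([t[2] for t in terms], axis=0)
    bio_export = np.mean([t[3] for t in terms], axis=0)
    # storage change of the bio component in the surface layer over the window
    dt_win = full_w[-1].year - full_w[0].year
    storage = (terms[-1][4] - terms[0][4]) / dt_win

    rows = {}
    closure = {}
    for name in [*basins, "Global"]:
        m = np.ones_like(masks[basins[0]], dtype=bool) if name == "Global" else masks[name]
        production = umol_to_tg(float(prod_col[m].sum()))
        flux = umol_to_tg(float(net_flux[m].sum()))
        emis = umol_to_tg(float(bio_emis[m].sum()))
        oxml = umol_to_tg(float(bio_ox[m].sum()))
        exp_transport = umol_to_tg(
            float(bio_export[m].sum()) - float(storage[m].sum())
            + float(prod_sub_col[m].sum())
        )
        rows[name] = {
            "production": production,
            "net_sea_air_flux": flux,
            "bio_emission": emis,
            "bio_ml_oxidation": oxml,
            "bio_export": exp_transport,
        }
        closure[name] = (
            abs(production - (emis + oxml + exp_transport)) / production
            if production > 0 else 0.0
        )
    table = pd.DataFrame(rows).T
    return BasinBudget(
        table=table,
        closure=pd.Series(closure),
        window_years=(full_w[0].year, full_w[-1].year),
    )


def fate_timescales(world, ox: OxidationParams, gx: GasExchangeOperator) -> pd.DataFrame:
    """Per-column timescale diagnostics explaining the fate partition.

    equilibration_days = d / (k_w (1 - f_ice)) — infinite under full ice
    cover (flagged); oxidation_years = 1/k_ox; ventilation_age_years is
    the ideal age of the column's deepest cell.  Emission dominates where
    equilibration is much faster than both alternatives.
    """
    grid = world.grid
    kw = gx.kw_m_per_d
    open_frac = 1.0 - gx.f_ice
    with np.errstate(divide="ignore"):
        t_eq = np.where(open_frac > 0, grid.top_thickness / (kw * np.where(open_frac > 0, open_frac, 1.0)), np.inf)
    t_ox = 1.0 / ox.k_ox if ox.k_ox > 0 else np.inf
    age = ideal_age(world.transport, grid)[-1]
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    return pd.DataFrame(
        {
            "lat": lat2.ravel(),
            "lon": lon2.ravel(),
            "equilibration_days": t_eq.ravel(),
            "ice_capped": (open_frac.ravel() == 0.0),
            "oxidation_years": t_ox,
            "ventilation_age_years": age.ravel(),
            "basin": grid.basin.ravel().astype(str),
        }
    )
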