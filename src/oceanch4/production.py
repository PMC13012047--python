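"""Oxic CH4 production parameterizations.

Six candidate mechanisms for methane release in oxygenated surface waters,
each with three free parameters and a depth horizon that confines the
source to the layer where the mechanism operates:

* ``npp``        — photosynthetic release, proportional to NPP with
                   separate yields per plankton size class (above z_eu);
* ``zoo``        — zooplankton gut egestion, scaling with biomass, a Q10
                   temperature factor, and Michaelis–Menten O2 limitation
                   (above z_DVM);
* ``dms``/``labile``/``semilabile`` — substrate-limited release during
                   microbial DOM cycling (DMSP, acetate-like labile DOC,
                   or MPn-like semilabile DOC), with a community break-even
                   threshold (above z_ML);
* ``po4``        — phosphate-inhibited methylphosphonate cleavage by the
                   C-P lyase pathway: a descending tanh of ambient PO4
                   (above z_ML).

Two combined variants: ``po4_semilabile`` multiplies the PO4-inhibition
curve by the semilabile substrate-limitation factor, and ``npp_plus_po4``
adds the photosynthetic and PO4-inhibited sources.

All rates are µmol CH4 m⁻³ y⁻¹ on the model grid, zero below the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BioFields",
    "ProductionConfig",
    "PATHWAY_PARAMS",
    "production_rate",
    "jprod_npp",
    "jprod_zoo",
    "jprod_substrate",
    "jprod_po4",
    "jprod_combined",
    "substrate_threshold",
]

#: zooplankton reference temperature (°C), fixed, not optimized
T_REF_ZOO = 20.0

#: free-parameter names per pathway (oxidation parameters are separate)
PATHWAY_PARAMS = {
    "none": (),
    "npp": ("a_m", "a_n", "a_p"),
    "zoo": ("a_zoo", "q10", "k_o2"),
    "dms": ("a_s", "k_s", "b_s"),
    "labile": ("a_s", "k_s", "b_s"),
    "semilabile": ("a_s", "k_s", "b_s"),
    "po4": ("a_0", "p_crit", "w"),
    "po4_semilabile": ("a_0", "p_crit", "w", "k_s"),
    "npp_plus_po4": ("a_m", "a_n", "a_p", "a_0", "p_crit", "w"),
}

_SUBSTRATE_FIELD = {"dms": "dms", "labile": "s_lab", "semilabile": "s_semi"}


@dataclass
class BioFields:
    """Biogeochemical input fields on the model grid.

    3-D arrays (nz, nlat, nlon): po4 (µM), npp (mgC m⁻³ d⁻¹) with size-class
    fractions f_m/f_n/f_p, b_z (zooplankton biomass, mgC m⁻³), temperature
    (°C), o2 (µM), s_lab / s_semi (labile / semilabile DOC, µM-C), dms (nM).
    2-D arrays (nlat, nlon): depth horizons z_ml, z_eu, z_dvm (m, positive).
    """

    po4: np.ndarray
    npp: np.ndarray
    f_m: np.ndarray
    f_n: np.ndarray
    f_p: np.ndarray
    b_z: np.ndarray
    temperature: np.ndarray
    o2: np.ndarray
    s_lab: np.ndarray
    s_semi: np.ndarray
    dms: np.ndarray
    z_ml: np.ndarray
    z_eu: np.ndarray
    z_dvm: np.ndarray

    def validate(self) -> None:
        for name in ("po4", "npp", "b_z", "o2", "s_lab", "s_semi", "dms"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        for name in ("z_ml", "z_eu", "z_dvm"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        has_npp = self.npp > 0
        fsum = self.f_m + self.f_n + self.f_p
        if not np.allclose(fsum[has_npp], 1.0, atol=1e-8):
            raise ValueError("functional-group fractions must sum to 1 where NPP > 0")


@dataclass
class ProductionConfig:
    """A pathway identifier and its free parameters.

    ``params`` keys must match :data:`PATHWAY_PARAMS` for the pathway.
    Rate parameters are nonnegative, q10 >= 1, 0 <= b_s < 1, w > 0.
    """

    pathway: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pathway not in PATHWAY_PARAMS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        expected = set(PATHWAY_PARAMS[self.pathway])
        got = set(self.params)
        if got != expected:
            raise ValueError(
                f"pathway {self.pathway!r} expects parameters {sorted(expected)}, got {sorted(got)}"
            )
        for k, v in self.params.items():
            if k == "b_s":
                if not 0.0 <= v < 1.0:
                    raise ValueError("b_s must lie in [0, 1)")
            elif k == "q10":
                if v < 1.0:
                    raise ValueError("q10 must be >= 1")
            elif k == "w":
                if v <= 0.0:
                    raise ValueError("tanh width w must be positive")
            elif v < 0.0:
                raise ValueError(f"parameter {k} must be nonnegative")


def horizon_mask(grid, horizon_2d: np.ndarray) -> np.ndarray:
    """Boolean (nz, nlat, nlon): cell center shallower than the horizon.

    Sharp cutoff at cell centers; no partial-cell weighting on this coarse
    grid.
    """
    return grid.depth[:, None, None] < horizon_2d[None, :, :]


def jprod_npp(fields: BioFields, p: ProductionConfig, grid) -> np.ndarray:
    """Photosynthetic production: (a_m f_m + a_n f_n + a_p f_p) * NPP above z_eu."""
    if p.pathway != "npp":
        raise ValueError("jprod_npp requires the 'npp' pathway")
    pp = p.params
    yields = pp["a_m"] * fields.f_m + pp["a_n"] * fields.f_n + pp["a_p"] * fields.f_p
    if np.any((fields.npp > 0) & ~np.isfinite(fields.f_m + fields.f_n + fields.f_p)):
        raise ValueError("functional-group fractions missing where NPP > 0")
    rate = yields * fields.npp
    return np.where(horizon_mask(grid, fields.z_eu), rate, 0.0)


def jprod_zoo(fields: BioFields, p: ProductionConfig, grid) -> np.ndarray:
    """Zooplankton egestion: a_zoo * B_z * Q10^((T-20)/10) * O2/(O2+k_O2) above z_DVM."""
    if p.pathway != "zoo":
        raise ValueError("jprod_zoo requires the 'zoo' pathway")
    if np.any(fields.o2 < 0):
        raise ValueError("negative O2")
    pp = p.params
    tfac = pp["q10"] ** ((fields.temperature - T_REF_ZOO) / 10.0)
    ofac = fields.o2 / (fields.o2 + pp["k_o2"])
    rate = pp["a_zoo"] * fields.b_z * tfac * ofac
    return np.where(horizon_mask(grid, fields.z_dvm), rate, 0.0)


def substrate_threshold(k_s: float, b_s: float) -> float:
    """Break-even substrate concentration b_s*K_s/(1-b_s) below which production stops."""
    return b_s * k_s / (1.0 - b_s)


def jprod_substrate(fields: BioFields, p: ProductionConfig, grid, substrate: str | None = None) -> np.ndarray:
    """Substrate-limited DOM cycling: a_s * f * max(0, f - b_s), f = S/(S+K_s).

    Applied above z_ML.  The rate is clamped at zero below the break-even
    concentration (production is a source, never a sink); it vanishes
    exactly when S <= b_s*K_s/(1-b_s) and saturates toward a_s*(1-b_s).
    """
    substrate = substrate or p.pathway
    if substrate not in _SUBSTRATE_FIELD:
        raise ValueError(f"substrate must be one of {sorted(_SUBSTRATE_FIELD)}")
    pp = p.params
    if pp["k_s"] <= 0:
        raise ValueError("half-saturation K_s must be positive")
    s = getattr(fields, _SUBSTRATE_FIELD[substrate])
    f = s / (s + pp["k_s"])
    rate = pp["a_s"] * f * np.maximum(0.0, f - pp["b_s"])
    return np.where(horizon_mask(grid, fields.z_ml), rate, 0.0)


def _po4_curve(po4, a_0: float, p_crit: float, w: float):
    """Descending tanh of PO4: a_0 * (0.5 - 0.5*tanh((PO4 - P_crit)/w)).

    a_0 is the theoretical maximum rate as PO4 -> 0 (up to the small
    tanh(-P_crit/w) offset), P_crit the inhibition midpoint, w the width.
    """
    if w <= 0:
        raise ValueError("tanh width w must be positive")
    return a_0 * (0.5 - 0.5 * np.tanh((po4 - p_crit) / w))


def jprod_po4(fields: BioFields, p: ProductionConfig, grid) -> np.ndarray:
    """PO4-inhibited MPn cleavage above z_ML; strictly decreasing in PO4."""
    if p.pathway != "po4":
        raise ValueError("jprod_po4 requires the 'po4' pathway")
    if np.any(fields.po4 < 0):
        raise ValueError("negative PO4")
    pp = p.params
    rate = _po4_curve(fields.po4, pp["a_0"], pp["p_crit"], pp["w"])
    return np.where(horizon_mask(grid, fields.z_ml), rate, 0.0)


def jprod_combined(fields: BioFields, p: ProductionConfig, grid) -> np.ndarray:
    """Combined variants.

    ``po4_semilabile``: the PO4-inhibition curve multiplied by the
    semilabile substrate-limitation factor f = S_semi/(S_semi + K_s)
    (limitation x inhibition; reduces to the po4 form as S_semi -> inf).
    ``npp_plus_po4``: sum of the photosynthetic and PO4-inhibited fields
    (independent sources; reduces to either constituent when the other's
    rate parameters are zero).
    """
    pp = p.params
    if p.pathway == "po4_semilabile":
        base = _po4_curve(fields.po4, pp["a_0"], pp["p_crit"], pp["w"])
        if pp["k_s"] <= 0:
            raise ValueError("half-saturation K_s must be positive")
        f = fields.s_semi / (fields.s_semi + pp["k_s"])
        return np.where(horizon_mask(grid, fields.z_ml), base * f, 0.0)
    if p.pathway == "npp_plus_po4":
        npp_cfg = ProductionConfig(
            "npp", {k: pp[k] for k in ("a_m", "a_n", "a_p")}
        )
        po4_cfg = ProductionConfig(
            "po4", {k: pp[k] for k in ("a_0", "p_crit", "w")}
        )
        return jprod_npp(fields, npp_cfg, grid) + jprod_po4(fields, po4_cfg, grid)
    raise ValueError("jprod_combined requires a combined pathway")


def production_rate(fields: BioFields, p: ProductionConfig, grid) -> np.ndarray:
    """Dispatch to the pathway's rate function; 'none' gives a zero field."""
    if p.pathway == "none":
        return np.zeros(grid.shape)
    if p.pathway == "npp":
        return jprod_npp(fields, p, grid)
    if p.pathway == "zoo":
        return jprod_zoo(fields, p, grid)
    if p.pathway in _SUBSTRATE_FIELD:
        return jprod_substrate(fields, p, grid)
    if p.pathway == "po4":
        return jprod_po4(fields, p, grid)
    return jprod_combined(fields, p, grid)
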