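"""Atmospheric history, solubility, and air–sea gas exchange.

The air–sea flux of CH4 is J_gx = Q_gx * (S_CH4 - C), where the saturation
concentration S_CH4 = X_CH4 * P * K follows Henry's law (X_CH4 the
atmospheric dry mole fraction, P the sea-level pressure, K the solubility),
and Q_gx = (1 - f_ice) * k_w / d is the exchange rate of the model's top
layer (thickness d).  The piston velocity k_w is quadratic in 10-m wind
speed and normalized by the Schmidt number at 660 (the 20 °C seawater CO2
reference).

Unit pipeline for saturation: X_CH4 in ppb is 1e-9 atm mole fraction at
P = 1 atm; K in mol L⁻¹ atm⁻¹ converts to mol L⁻¹, and 1 mol L⁻¹ =
1e9 µmol m⁻³, so numerically S[µmol m⁻³] = X[ppb] * P[atm] * K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import DAYS_PER_YEAR

__all__ = [
    "AtmosphereHistory",
    "ForcingFields",
    "GasExchangeOperator",
    "solubility",
    "schmidt_number",
    "piston_velocity",
    "saturation",
    "gas_exchange_operator",
    "WG79_CH4_BUNSEN",
    "W14_CH4_SCHMIDT",
]

#: Bunsen solubility coefficient fit for CH4 in seawater
#: (Wiesenburg & Guinasso 1979): ln(beta) = A1 + A2*(100/T) + A3*ln(T/100)
#: + S*(B1 + B2*(T/100) + B3*(T/100)^2), T in kelvin, S in psu.
WG79_CH4_BUNSEN = {
    "A1": -68.8862,
    "A2": 101.4956,
    "A3": 28.7314,
    "B1": -0.076146,
    "B2": 0.043970,
    "B3": -0.0068672,
}

#: Molar volume used to convert the (dimensionless) Bunsen coefficient to
#: mol L⁻¹ atm⁻¹ (ideal gas at STP, L mol⁻¹).
MOLAR_VOLUME_STP = 22.414

#: 4th-order Schmidt-number polynomial in SST (°C) for CH4 in seawater
#: (Wanninkhof 2014 family, same provenance as the 0.251 piston-velocity
#: coefficient and the Sc/660 normalization).
W14_CH4_SCHMIDT = (2101.2, -131.54, 4.4931, -0.08676, 0.00070663)

_SST_RANGE = (-2.0, 40.0)
_SAL_RANGE = (0.0, 42.0)


def solubility(sst, sal, coeffs: dict | None = None):
    """CH4 solubility K (mol L⁻¹ atm⁻¹) from SST (°C) and salinity (psu).

    Strictly decreasing in temperature at fixed salinity: cold polar water
    holds roughly 1.5-1.8x more CH4 at equilibrium than warm tropical water.
    ``coeffs`` overrides the default Bunsen-fit coefficient set.

    Raises ValueError outside sst ∈ [-2, 40] °C or sal ∈ [0, 42] psu.
    """
    sst = np.asarray(sst, dtype=float)
    sal = np.asarray(sal, dtype=float)
    if np.any(sst < _SST_RANGE[0]) or np.any(sst > _SST_RANGE[1]):
        raise ValueError(f"SST outside valid range {_SST_RANGE} °C")
    if np.any(sal < _SAL_RANGE[0]) or np.any(sal > _SAL_RANGE[1]):
        raise ValueError(f"salinity outside valid range {_SAL_RANGE} psu")
    t_k = sst + 273.15
    c = coeffs or WG79_CH4_BUNSEN
    ln_beta = (
        c["A1"]
        + c["A2"] * (100.0 / t_k)
        + c["A3"] * np.log(t_k / 100.0)
        + sal * (c["B1"] + c["B2"] * (t_k / 100.0) + c["B3"] * (t_k / 100.0) ** 2)
    )
    return np.exp(ln_beta) / MOLAR_VOLUME_STP


def schmidt_number(sst, coeffs: tuple | None = None):
    """Schmidt number for CH4 in seawater as a polynomial in SST (°C).

    Sc(20 °C) = 686.62 with the default coefficients; strictly decreasing
    over the valid range [-2, 40] °C.  ``coeffs`` overrides the default
    quartic coefficient set.
    """
    sst = np.asarray(sst, dtype=float)
    if np.any(sst < _SST_RANGE[0]) or np.any(sst > _SST_RANGE[1]):
        raise ValueError(f"SST outside valid range {_SST_RANGE} °C")
    a, b, c, d, e = coeffs or W14_CH4_SCHMIDT
    return a + b * sst + c * sst**2 + d * sst**3 + e * sst**4


def piston_velocity(u10, sc):
    """Gas-transfer (piston) velocity k_w in m d⁻¹.

    k_w = 0.251 * U^2 * (Sc/660)^(-1/2) in cm h⁻¹, converted to m d⁻¹
    (x 24/100).  U is the 10-m wind speed in m s⁻¹.
    """
    u10 = np.asarray(u10, dtype=float)
    sc = np.asarray(sc, dtype=float)
    if np.any(u10 < 0):
        raise ValueError("wind speed must be nonnegative")
    if np.any(sc <= 0):
        raise ValueError("Schmidt number must be positive")
    kw_cm_per_h = 0.251 * u10**2 * (sc / 660.0) ** -0.5
    return kw_cm_per_h * 24.0 / 100.0


def saturation(x_ch4_ppb, pressure_atm, k_sol):
    """Saturation concentration S_CH4 (µmol m⁻³ ≡ nM).

    S = X_CH4 * P * K; the ppb -> atm factor (1e-9) cancels against the
    mol L⁻¹ -> µmol m⁻³ factor (1e9), so the product is taken directly.
    Linear in each argument; zero atmosphere gives zero saturation.
    """
    return np.asarray(x_ch4_ppb, dtype=float) * np.asarray(pressure_atm, dtype=float) * np.asarray(k_sol, dtype=float)


@dataclass(frozen=True)
class AtmosphereHistory:
    """Annual-mean atmospheric CH4 mixing ratio (ppb) vs. year.

    Years must be strictly increasing and values positive.  Between
    tabulated years the mixing ratio is linearly interpolated; before the
    first year it is held constant at the first value (the preindustrial
    spin-up constant, 706 ppb at 1700 by default).
    """

    years: np.ndarray
    ppb: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=float)
        ppb = np.asarray(self.ppb, dtype=float)
        if years.ndim != 1 or years.shape != ppb.shape:
            raise ValueError("years and ppb must be 1-D arrays of equal length")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(ppb <= 0):
            raise ValueError("mixing ratios must be positive")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "ppb", ppb)

    def value(self, year):
        """Mixing ratio (ppb) at ``year`` (scalar or array)."""
        return np.interp(year, self.years, self.ppb)

    @property
    def preindustrial_ppb(self) -> float:
        return float(self.ppb[0])

    @classmethod
    def synthetic(
        cls,
        year0: float = 1700.0,
        ppb0: float = 706.0,
        year1: float = 2014.0,
        ppb1: float = 1832.0,
        shape_exponent: float = 4.0,
    ) -> "AtmosphereHistory":
        """Smooth accelerating rise from (year0, ppb0) to (year1, ppb1).

        X(t) = ppb0 + (ppb1 - ppb0) * ((t - year0)/(year1 - year0))^p, a
        power-law that mimics the slow pre-1900 drift and steep 20th-century
        growth of the ice-core + instrumental CH4 record.  Tabulated every
        10 y to 1950 and annually afterwards.
        """
        if ppb1 < ppb0:
            raise ValueError("history must be non-decreasing: ppb1 >= ppb0")
        years = np.concatenate(
            [np.arange(year0, 1950.0, 10.0), np.arange(1950.0, year1 + 0.5, 1.0)]
        )
        frac = (years - year0) / (year1 - year0)
        ppb = ppb0 + (ppb1 - ppb0) * frac**shape_exponent
        return cls(years=years, ppb=ppb)

    @classmethod
    def from_csv(cls, path) -> "AtmosphereHistory":
        """Read a 2-column (year, ppb) CSV."""
        df = pd.read_csv(path)
        return cls(years=df.iloc[:, 0].to_numpy(), ppb=df.iloc[:, 1].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"year": self.years, "ppb": self.ppb}).to_csv(path, index=False)


@dataclass
class ForcingFields:
    """Per-surface-cell physical forcing (2-D arrays, nlat x nlon).

    sst (°C), salinity (psu), u10 (m s⁻¹), f_ice (fraction), pressure (atm).
    """

    sst: np.ndarray
    salinity: np.ndarray
    u10: np.ndarray
    f_ice: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        if np.any(self.f_ice < 0) or np.any(self.f_ice > 1):
            raise ValueError("f_ice must lie in [0, 1]")
        if np.any(self.u10 < 0):
            raise ValueError("wind speed must be nonnegative")
        if np.any(self.pressure <= 0):
            raise ValueError("pressure must be positive")


@dataclass
class GasExchangeOperator:
    """Surface gas-exchange rate Q_gx (y⁻¹) and the saturation field.

    qgx_surface is (nlat, nlon); the operator is zero below the top layer.
    ``saturation_surface(x_ppb)`` gives S_CH4 for a mixing ratio, so the
    surface source term of the tracer equation is qgx * (S - C).
    """

    qgx_surface: np.ndarray
    k_sol_surface: np.ndarray
    pressure: np.ndarray
    kw_m_per_d: np.ndarray
    top_thickness: float
    f_ice: np.ndarray

    def __post_init__(self):
        if np.any(self.qgx_surface < 0):
            raise ValueError("Q_gx must be nonnegative")

    def saturation_surface(self, x_ch4_ppb: float) -> np.ndarray:
        """S_CH4 (µmol m⁻³) per surface cell for mixing ratio x (ppb)."""
        return saturation(x_ch4_ppb, self.pressure, self.k_sol_surface)

    def qgx_flat(self, grid) -> np.ndarray:
        """Q_gx extended to the full wet-cell vector (zero below surface)."""
        full = np.zeros(grid.shape)
        full[0] = self.qgx_surface
        return full.ravel()

    def saturation_flat(self, grid, x_ch4_ppb: float) -> np.ndarray:
        full = np.zeros(grid.shape)
        full[0] = self.saturation_surface(x_ch4_ppb)
        return full.ravel()


def gas_exchange_operator(forcing: ForcingFields, grid) -> GasExchangeOperator:
    """Assemble Q_gx = (1 - f_ice) * k_w / d on the surface layer (y⁻¹)."""
    sc = schmidt_number(forcing.sst)
    kw = piston_velocity(forcing.u10, sc)  # m/d
    qgx = (1.0 - forcing.f_ice) * kw * DAYS_PER_YEAR / grid.top_thickness
    k_sol = solubility(forcing.sst, forcing.salinity)
    return GasExchangeOperator(
        qgx_surface=qgx,
        k_sol_surface=k_sol,
        pressure=forcing.pressure,
        kw_m_per_d=kw,
        top_thickness=grid.top_thickness,
        f_ice=forcing.f_ice,
    )
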