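"""Synthetic ocean: grid, circulation, forcing and biogeochemical fields.

Everything downstream (spin-up, transient runs, calibration, budgets,
projections) is exercised on this desk-scale aqua-planet world, so no
external data products are required.  The world reproduces the pattern
classes the real analysis relies on:

* a mass-conserving overturning circulation with polar sinking, low-
  latitude upwelling and shallow subtropical-gyre downwelling, giving
  centuries-scale deep ventilation ages;
* surface phosphate with subtropical-gyre minima (< 0.1 µM, lowest in the
  North Atlantic gyre) and Southern-Ocean / tropical-upwelling maxima
  (> 1 µM), with NPP following the nutrient supply — so an NPP-linked
  methane source and a PO4-inhibited source predict distinct geographic
  patterns, which is what makes the pathways discriminable;
* a rising atmospheric CH4 history and noisy synthetic cruise transects
  sampled from a known-truth model run.

All outputs are pure functions of the configuration and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xarray as xr

from .forcing import AtmosphereHistory, ForcingFields
from .model import ModelState, TransportOperator
from .production import BioFields

__all__ = [
    "Grid",
    "WorldConfig",
    "World",
    "make_grid",
    "make_circulation",
    "make_fields",
    "make_cruises",
    "build_world",
    "ideal_age",
    "default_cruise_plan",
]

EARTH_RADIUS = 6.371e6  # m
SECONDS_PER_YEAR = 3.15576e7
SV_TO_M3_PER_YEAR = 1e6 * SECONDS_PER_YEAR

REGIONS = ("ANT", "NATL", "TPAC", "STPAC", "TATL", "STATL", "other")
BASINS = ("Pacific", "Atlantic", "Indian", "Southern")


@dataclass
class Grid:
    """Regular lat/lon/depth aqua-planet grid; all cells are wet.

    Depths are cell centers, m, positive downward; the top-layer thickness
    is a single scalar shared by all surface cells (36.14 m by default).
    Region and basin labels are per water column.
    """

    lat: np.ndarray
    lon: np.ndarray
    depth: np.ndarray
    lat_edges: np.ndarray
    lon_edges: np.ndarray
    depth_edges: np.ndarray
    dz: np.ndarray
    area: np.ndarray      # (nlat, nlon) m²
    volume: np.ndarray    # (nz, nlat, nlon) m³
    region: np.ndarray    # (nlat, nlon) str
    basin: np.ndarray     # (nlat, nlon) str

    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def nlon(self) -> int:
        return self.lon.size

    @property
    def nz(self) -> int:
        return self.depth.size

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.nlat, self.nlon)

    @property
    def n_cells(self) -> int:
        return self.nz * self.nlat * self.nlon

    @property
    def top_thickness(self) -> float:
        return float(self.dz[0])

    @property
    def volumes_flat(self) -> np.ndarray:
        return self.volume.ravel()

    def surface_mask_flat(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[0] = True
        return m.ravel()

    def index(self, k: int, j: int, i: int) -> int:
        return (k * self.nlat + j) * self.nlon + i

    def column_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Nearest water column (j, i) for a position; lon wraps at 360."""
        j = int(np.argmin(np.abs(self.lat - lat)))
        dlon = np.abs((self.lon - lon + 180.0) % 360.0 - 180.0)
        i = int(np.argmin(dlon))
        return j, i


def _basin_of(lat: float, lon: float) -> str:
    if lat < -45.0:
        return "Southern"
    lon = lon % 360.0
    if 290.0 <= lon or lon < 20.0:
        return "Atlantic"
    if 20.0 <= lon < 145.0:
        return "Indian"
    return "Pacific"


def _region_of(lat: float, basin: str) -> str:
    if lat <= -45.0:
        return "ANT"
    a = abs(lat)
    if basin == "Atlantic":
        if lat >= 45.0:
            return "NATL"
        return "TATL" if a < 15.0 else "STATL"
    if basin == "Pacific":
        if a < 15.0:
            return "TPAC"
        if a < 45.0:
            return "STPAC"
    return "other"


@dataclass
class CruiseTrack:
    """One planned transect: a year, a longitude, a latitude span, and the
    station sampling depths."""

    cruise_id: str
    year: float
    lon: float
    lat_start: float
    lat_end: float
    n_stations: int
    depths: tuple


def default_cruise_plan() -> list[CruiseTrack]:
    """Eleven tracks spanning polar to subtropical waters in all basins,
    mirroring the coverage the real transect archive provides.  Every
    track samples to at least 1,000 m; five resolve the near-full column.
    """
    shallow = (10.0, 30.0, 60.0, 100.0, 150.0, 250.0, 400.0, 600.0, 1000.0)
    deep = shallow + (2000.0, 3000.0, 3800.0)
    return [
        CruiseTrack("ATL-MERID", 1995.0, 340.0, -50.0, 50.0, 13, deep),
        CruiseTrack("PAC-MERID", 1991.0, 200.0, -40.0, 40.0, 11, deep),
        CruiseTrack("SO-ANT", 1999.0, 100.0, -78.0, -50.0, 7, shallow),
        CruiseTrack("NATL-SUBPOL", 1997.0, 330.0, 45.0, 80.0, 8, deep),
        CruiseTrack("IND-MERID", 1996.0, 70.0, -40.0, 10.0, 10, shallow),
        CruiseTrack("NPAC-GYRE", 1993.0, 170.0, 10.0, 40.0, 8, shallow),
        CruiseTrack("NATL-GYRE", 2001.0, 315.0, 15.0, 40.0, 8, shallow),
        CruiseTrack("SPAC-GYRE", 1998.0, 230.0, -40.0, -10.0, 8, deep),
        CruiseTrack("TATL", 2003.0, 345.0, -15.0, 15.0, 7, shallow),
        CruiseTrack("NPAC-SUBPOL", 1994.0, 180.0, 40.0, 75.0, 8, deep),
        CruiseTrack("SIND", 2000.0, 90.0, -45.0, -15.0, 8, shallow),
    ]


@dataclass
class WorldConfig:
    """Everything that defines the synthetic world, including its seed.

    Circulation strengths are volume transports in Sverdrups; diffusivities
    in m² s⁻¹.  Field-shape parameters control the latitudinal structure of
    the surface fields; the atmospheric history is a power-law rise between
    its endpoints.  All outputs are deterministic functions of (config, seed).
    """

    nlat: int = 24
    nlon: int = 16
    nz: int = 8
    top_thickness: float = 36.14
    # circulation
    overturning_sv: float = 40.0
    gyre_sv: float = 20.0
    kappa_h: float = 2000.0        # horizontal diffusivity, m² s⁻¹
    kappa_v: float = 2e-5          # background vertical diffusivity, m² s⁻¹
    kappa_v_polar: float = 3e-3    # deep-mixing diffusivity poleward of polar_lat
    polar_lat: float = 60.0
    gyre_center_lat: float = 35.0
    gyre_width_deg: float = 10.0
    gyre_depth_m: float = 500.0
    # field shapes
    po4_southern_max: float = 1.8
    po4_gyre_min: float = 0.05
    po4_deep: float = 2.3
    include_omz: bool = False
    # atmosphere
    atm_year0: float = 1700.0
    atm_ppb0: float = 706.0
    atm_year1: float = 2014.0
    atm_ppb1: float = 1832.0
    atm_shape_exponent: float = 4.0
    # cruise plan
    cruise_plan: list = field(default_factory=default_cruise_plan)
    noise_sd: float = 0.1          # nM, vial-sample 1-SD measurement scale
    noise_profile: str = "constant"  # or "surface_enhanced"
    seed: int = 0

    def __post_init__(self):
        for name in ("overturning_sv", "gyre_sv", "kappa_h", "kappa_v", "kappa_v_polar", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.atm_ppb1 < self.atm_ppb0:
            raise ValueError("atmospheric history must be non-decreasing")

    def atmosphere(self) -> AtmosphereHistory:
        return AtmosphereHistory.synthetic(
            self.atm_year0, self.atm_ppb0, self.atm_year1, self.atm_ppb1,
            self.atm_shape_exponent,
        )


def make_grid(cfg: WorldConfig) -> Grid:
    """Build the aqua-planet grid.

    Layer thicknesses thicken geometrically below the fixed top layer to
    cover ~4 km of water column; a single-layer configuration (nz=1) is a
    valid degenerate case in which every cell is a surface cell.
    """
    if cfg.nlat < 2 or cfg.nlon < 2 or cfg.nz < 1:
        raise ValueError("grid dimensions must be >= 2 horizontally and >= 1 vertically")
    lat_edges = np.linspace(-90.0, 90.0, cfg.nlat + 1)
    lon_edges = np.linspace(0.0, 360.0, cfg.nlon + 1)
    lat = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    if cfg.nz == 1:
        dz = np.array([cfg.top_thickness])
    else:
        # geometric thickening below the top layer, scaled to ~4,000 m total
        ratios = 1.65 ** np.arange(cfg.nz - 1)
        rest = ratios / ratios.sum() * (4000.0 - cfg.top_thickness)
        dz = np.concatenate([[cfg.top_thickness], rest])
    depth_edges = np.concatenate([[0.0], np.cumsum(dz)])
    depth = 0.5 * (depth_edges[:-1] + depth_edges[1:])

    phi = np.deg2rad(lat_edges)
    dlam = np.deg2rad(lon_edges[1] - lon_edges[0])
    band = EARTH_RADIUS**2 * dlam * (np.sin(phi[1:]) - np.sin(phi[:-1]))
    area = np.repeat(band[:, None], cfg.nlon, axis=1)
    volume = dz[:, None, None] * area[None, :, :]

    basin = np.empty((cfg.nlat, cfg.nlon), dtype=object)
    region = np.empty((cfg.nlat, cfg.nlon), dtype=object)
    for j in range(cfg.nlat):
        for i in range(cfg.nlon):
            b = _basin_of(lat[j], lon[i])
            basin[j, i] = b
            region[j, i] = _region_of(lat[j], b)
    return Grid(
        lat=lat, lon=lon, depth=depth,
        lat_edges=lat_edges, lon_edges=lon_edges, depth_edges=depth_edges,
        dz=dz, area=area, volume=volume, region=region, basin=basin,
    )


def _streamfunction(cfg: WorldConfig, grid: Grid) -> np.ndarray:
    """Zonally integrated overturning streamfunction psi on the
    (lat_edge, depth_edge) corners, m³ y⁻¹, zero on all boundaries.

    Deep cells: polar sinking, low-latitude upwelling in each hemisphere.
    Gyre cells: shallow downwelling on the equatorward flank of the
    subtropical gyres, confined to the upper ``gyre_depth_m``.
    """
    h = grid.depth_edges[-1]
    phi = grid.lat_edges[:, None]            # (nlat+1, 1)
    z = grid.depth_edges[None, :]            # (1, nz+1)
    zeta = z / h
    psi_deep = (
        cfg.overturning_sv * SV_TO_M3_PER_YEAR
        * np.sin(np.pi * zeta) * np.sin(np.pi * phi / 90.0)
    )
    zeta_g = np.minimum(z / cfg.gyre_depth_m, 1.0)
    gyre_shape = np.exp(-(((np.abs(phi) - cfg.gyre_center_lat) / cfg.gyre_width_deg) ** 2))
    psi_gyre = (
        -cfg.gyre_sv * SV_TO_M3_PER_YEAR
        * np.sin(np.pi * zeta_g) * gyre_shape * np.sign(phi)
    )
    psi = psi_deep + psi_gyre
    psi[0, :] = psi[-1, :] = 0.0
    psi[:, 0] = psi[:, -1] = 0.0
    return psi


def make_circulation(grid: Grid, cfg: WorldConfig) -> TransportOperator:
    """Assemble the sparse transport operator A (y⁻¹).

    Advection follows the discrete overturning streamfunction (fluxes on
    faces are differences of corner psi values, so the velocity field is
    divergence-free and A applied to a uniform tracer vanishes exactly);
    upwind differencing keeps the scheme monotone.  Diffusion is a
    pairwise-exchange stencil (horizontal, vertical, and enhanced vertical
    mixing poleward of ``polar_lat`` to mimic deep convection).  Both
    pieces are antisymmetric in volume flux, so vol^T A = 0 to machine
    precision and total moles change only through sources and sinks.
    """
    nz, nlat, nlon = grid.shape
    vol = grid.volumes_flat
    n = grid.n_cells
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(np.atleast_1d(r))
        cols.append(np.atleast_1d(c))
        vals.append(np.atleast_1d(np.asarray(v, dtype=float)))

    def add_flux(i_from: int, i_to: int, phi_m3y: float):
        """Upwind advective transport phi (m³ y⁻¹) from cell i_from to i_to."""
        if phi_m3y == 0.0:
            return
        if phi_m3y < 0.0:
            i_from, i_to, phi_m3y = i_to, i_from, -phi_m3y
        add(i_to, i_from, phi_m3y / vol[i_to])
        add(i_from, i_from, -phi_m3y / vol[i_from])

    def add_exchange(i_a: int, i_b: int, e_m3y: float):
        """Symmetric diffusive exchange e (m³ y⁻¹) between two cells."""
        if e_m3y <= 0.0:
            return
        add(i_a, i_b, e_m3y / vol[i_a])
        add(i_a, i_a, -e_m3y / vol[i_a])
        add(i_b, i_a, e_m3y / vol[i_b])
        add(i_b, i_b, -e_m3y / vol[i_b])

    psi = _streamfunction(cfg, grid)  # (nlat+1, nz+1)
    per_lon = 1.0 / nlon

    # advection: meridional faces (between j and j+1) and vertical faces
    for j_e in range(1, nlat):
        for k in range(nz):
            v_north = (psi[j_e, k + 1] - psi[j_e, k]) * per_lon
            if v_north == 0.0:
                continue
            for i in range(nlon):
                add_flux(grid.index(k, j_e - 1, i), grid.index(k, j_e, i), v_north)
    for k_e in range(1, nz):
        for j in range(nlat):
            w_up = (psi[j + 1, k_e] - psi[j, k_e]) * per_lon
            if w_up == 0.0:
                continue
            for i in range(nlon):
                # positive = upward: from layer k_e (below edge) to k_e - 1
                add_flux(grid.index(k_e, j, i), grid.index(k_e - 1, j, i), w_up)

    # diffusion
    kh_m2y = cfg.kappa_h * SECONDS_PER_YEAR
    dphi_m = EARTH_RADIUS * np.deg2rad(grid.lat[1] - grid.lat[0]) if nlat > 1 else 1.0
    dlam = np.deg2rad(grid.lon_edges[1] - grid.lon_edges[0])
    for k in range(nz):
        for j in range(nlat):
            for i in range(nlon):
                me = grid.index(k, j, i)
                # meridional neighbor
                if j + 1 < nlat:
                    face = grid.dz[k] * EARTH_RADIUS * dlam * np.cos(np.deg2rad(grid.lat_edges[j + 1]))
                    add_exchange(me, grid.index(k, j + 1, i), kh_m2y * face / dphi_m)
                # zonal neighbor (periodic)
                i2 = (i + 1) % nlon
                dx = EARTH_RADIUS * dlam * max(np.cos(np.deg2rad(grid.lat[j])), 0.05)
                face = grid.dz[k] * dphi_m
                add_exchange(me, grid.index(k, j, i2), kh_m2y * face / dx)
                # vertical neighbor
                if k + 1 < nz:
                    kv = cfg.kappa_v_polar if abs(grid.lat[j]) >= cfg.polar_lat else cfg.kappa_v
                    dzc = grid.depth[k + 1] - grid.depth[k]
                    add_exchange(me, grid.index(k + 1, j, i),
                                 kv * SECONDS_PER_YEAR * grid.area[j, i] / dzc)

    if vals:
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    else:  # all circulation strengths zero: the null operator
        mat = sp.csr_matrix((n, n))
    op = TransportOperator(matrix=mat, volumes=vol)
    defect = op.conservation_defect(np.ones(n))
    if defect > 1e-10:
        raise RuntimeError(f"transport assembly not conservative: defect {defect:.2e}")
    return op


def ideal_age(transport: TransportOperator, grid: Grid) -> np.ndarray:
    """Ventilation (ideal) age field, years: A·age = -1 with surface age 0.

    Deep ages are centuries-scale under the default circulation, oldest in
    low-latitude deep water and youngest under the polar sinking regions —
    the ordering the oxidation/ventilation competition depends on.
    """
    surf = grid.surface_mask_flat()
    interior = ~surf
    a_ii = transport.matrix[interior][:, interior]
    age = np.zeros(grid.n_cells)
    age[interior] = sp.linalg.spsolve(a_ii.tocsc(), -np.ones(int(interior.sum())))
    return age.reshape(grid.shape)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(x))


def make_fields(grid: Grid, cfg: WorldConfig) -> tuple[BioFields, ForcingFields]:
    """Surface-forced biogeochemical and physical fields with realistic
    latitudinal structure.

    Phosphate: Southern-Ocean and subpolar maxima, equatorial-upwelling
    bumps (strongest in the Pacific), and subtropical-gyre minima with the
    global minimum in the North Atlantic gyre; increases toward a uniform
    deep value with depth.  NPP follows the macronutrient supply, so the
    oligotrophic gyres are low-NPP as well as low-PO4, while the gyre-
    peaked PO4-inhibition pattern is spatially distinct from NPP — the
    contrast that lets calibration discriminate the pathways.  All fields
    are clamped to physical ranges rather than raising.
    """
    lat = grid.lat[:, None] * np.ones((1, grid.nlon))
    depth = grid.depth[:, None, None]
    a = np.abs(lat)

    # --- physical surface fields
    sst = np.clip(29.0 * np.cos(np.deg2rad(lat)) ** 1.5 - 1.0, -1.8, None)
    sal = (35.0 + 1.5 * np.exp(-(((a - 25.0) / 15.0) ** 2))
           - 1.0 * np.exp(-((lat / 10.0) ** 2)) - 0.8 * (a > 60.0))
    u10 = 7.0 + 5.0 * np.exp(-(((a - 50.0) / 12.0) ** 2)) - 3.0 * np.exp(-((lat / 12.0) ** 2))
    f_ice = np.clip((a - 65.0) / 25.0, 0.0, 1.0) * 0.9
    pressure = np.ones_like(lat)
    forcing = ForcingFields(sst=sst, salinity=sal, u10=u10, f_ice=f_ice, pressure=pressure)

    # --- surface phosphate (µM)
    is_atl = np.isin(grid.basin, ["Atlantic"])
    is_pac = np.isin(grid.basin, ["Pacific"])
    eq_bump = np.where(is_pac, 0.65, np.where(is_atl, 0.25, 0.40))
    # the high-PO4 (inhibited) transition sits equatorward of where the
    # wintertime mixed layer deepens, so subsurface production never meets
    # weakly ventilated water — as in the real subpolar oceans
    po4_surf = (
        cfg.po4_gyre_min
        + (cfg.po4_southern_max - cfg.po4_gyre_min) * _sigmoid((-lat - 42.0) / 4.0)
        + 0.90 * _sigmoid((lat - 42.0) / 5.0)
        + eq_bump * np.exp(-((lat / 8.0) ** 2))
        - 0.02 * (is_atl & (lat > 10.0) & (lat < 45.0))
        + 0.10 * (is_pac & (a > 15.0) & (a < 45.0))
    )
    po4_surf = np.clip(po4_surf, 0.01, None)
    po4 = po4_surf[None] + (cfg.po4_deep - po4_surf[None]) * (1.0 - np.exp(-depth / 800.0))

    # --- NPP (volumetric, mgC m⁻³ d⁻¹) tied to nutrient supply
    npp_surf = 1.5 + 14.0 * po4_surf / (po4_surf + 0.3)
    z_eu = 45.0 + 75.0 * np.exp(-po4_surf / 0.4)
    z_ml = 45.0 + 455.0 * _sigmoid((a - 50.0) / 6.0)
    z_dvm = 150.0 + 350.0 * np.exp(-((lat / 45.0) ** 2))
    npp = np.where(depth < z_eu[None], npp_surf[None] * np.exp(-depth / 120.0), 0.0)

    # functional-group split: picoplankton dominate oligotrophic gyres,
    # microplankton the nutrient-rich high latitudes
    w_p = 0.25 + 0.60 * np.exp(-po4_surf / 0.2)
    w_m = 0.10 + 0.60 * po4_surf / (po4_surf + 0.6)
    w_n = 0.30 * np.ones_like(po4_surf)
    tot = w_p + w_m + w_n
    f_p = np.broadcast_to((w_p / tot)[None], grid.shape).copy()
    f_m = np.broadcast_to((w_m / tot)[None], grid.shape).copy()
    f_n = np.broadcast_to((w_n / tot)[None], grid.shape).copy()

    b_z_surf = 2.0 + 0.8 * npp_surf
    b_z = np.where(depth < z_dvm[None], b_z_surf[None] * np.exp(-depth / 400.0), 0.0)

    temperature = 2.0 + (sst[None] - 2.0) * np.exp(-depth / 500.0)

    o2_surf = 320.0 - 6.0 * sst
    aou = 170.0 * np.exp(-(((depth - 800.0) / 700.0) ** 2)) * np.exp(-((lat[None] / 40.0) ** 2))
    o2 = np.clip(o2_surf[None] - aou, 20.0, None)
    if cfg.include_omz:
        # carve an OMZ patch in the eastern tropical Pacific thermocline
        omz_cols = is_pac & (a < 12.0) & (grid.lon[None, :] > 240.0)
        omz_depth = (grid.depth > 100.0) & (grid.depth < 1200.0)
        mask3 = omz_depth[:, None, None] & omz_cols[None, :, :]
        o2 = np.where(mask3, 3.0, o2)

    s_lab_surf = 1.0 + 7.0 * np.exp(-((lat / 25.0) ** 2))
    s_lab = np.where(depth < z_ml[None], s_lab_surf[None] * np.exp(-depth / 150.0), 0.0)
    s_semi_surf = 3.0 + 9.0 * np.exp(-(((a - 27.0) / 14.0) ** 2)) + 1.5 * np.exp(-((lat / 10.0) ** 2))
    s_semi = np.where(depth < z_ml[None], s_semi_surf[None] * np.exp(-depth / 300.0), 0.0)
    dms_surf = 1.0 + 0.25 * npp_surf
    dms = np.where(depth < z_ml[None], dms_surf[None], 0.0)

    bio = BioFields(
        po4=po4, npp=npp, f_m=f_m, f_n=f_n, f_p=f_p, b_z=b_z,
        temperature=temperature, o2=o2, s_lab=s_lab, s_semi=s_semi, dms=dms,
        z_ml=z_ml, z_eu=z_eu, z_dvm=z_dvm,
    )
    bio.validate()
    return bio, forcing


@dataclass
class World:
    """Bundle of everything a model run needs, tagged with its config."""

    config: WorldConfig
    grid: Grid
    transport: TransportOperator
    bio: BioFields
    forcing: ForcingFields
    atmosphere: AtmosphereHistory


def build_world(cfg: WorldConfig | None = None) -> World:
    """Construct the full synthetic world from a configuration."""
    cfg = cfg or WorldConfig()
    grid = make_grid(cfg)
    transport = make_circulation(grid, cfg)
    bio, forcing = make_fields(grid, cfg)
    return World(
        config=cfg, grid=grid, transport=transport,
        bio=bio, forcing=forcing, atmosphere=cfg.atmosphere(),
    )


def make_cruises(
    truth_states: list[ModelState],
    grid: Grid,
    cfg: WorldConfig,
):
    """Sample synthetic cruise transects from a known-truth run.

    Each planned track is sampled at its stations and depths by the same
    space/time interpolation used for real observations; Gaussian noise
    with the configured sd is added (optionally enhanced in the top 100 m
    where real-world variability is largest).  Samples are clipped at zero
    (a concentration cannot be negative).  With sd = 0 the samples equal
    the interpolated truth exactly, and a fixed seed reproduces the same
    transects.
    """
    from .observations import CruiseTransect, sample_model

    years = [s.year for s in truth_states]
    rng = np.random.default_rng(cfg.seed)
    cruises = []
    for track in cfg.cruise_plan:
        if not (min(years) <= track.year <= max(years)):
            raise ValueError(
                f"cruise {track.cruise_id} year {track.year} outside the "
                f"simulated span [{min(years)}, {max(years)}]"
            )
        lats = np.linspace(track.lat_start, track.lat_end, track.n_stations)
        depths = np.asarray(track.depths)
        lat_s = np.repeat(lats, depths.size)
        lon_s = np.full(lat_s.size, track.lon % 360.0)
        dep_s = np.tile(depths, lats.size)
        transect = CruiseTransect(
            cruise_id=track.cruise_id, year=track.year,
            lat=lat_s, lon=lon_s, depth=dep_s,
            ch4=np.zeros(lat_s.size), sd=np.zeros(lat_s.size),
        )
        truth = sample_model(truth_states, transect, grid)
        if cfg.noise_profile == "surface_enhanced":
            sd = np.where(dep_s <= 100.0, 1.5 * cfg.noise_sd, cfg.noise_sd)
        else:
            sd = np.full(lat_s.size, cfg.noise_sd)
        ch4 = truth + rng.normal(0.0, 1.0, size=truth.size) * sd
        cruises.append(
            CruiseTransect(
                cruise_id=track.cruise_id, year=track.year,
                lat=lat_s, lon=lon_s, depth=dep_s,
                ch4=np.clip(ch4, 0.0, None), sd=sd,
            )
        )
    return cruises


# ---------------------------------------------------------------------------
# I/O: NetCDF world file, sparse-triplet transport, cruise CSV

def world_to_netcdf(world: World, path) -> None:
    """Write grid, forcing and biogeochemical fields as NetCDF; the seed
    and configuration scalars ride along as attributes."""
    g = world.grid
    coords = {"depth": g.depth, "lat": g.lat, "lon": g.lon}
    dims3 = ("depth", "lat", "lon")
    dims2 = ("lat", "lon")
    b = world.bio
    f = world.forcing
    ds = xr.Dataset(
        {
            "po4": (dims3, b.po4), "npp": (dims3, b.npp),
            "f_m": (dims3, b.f_m), "f_n": (dims3, b.f_n), "f_p": (dims3, b.f_p),
            "b_z": (dims3, b.b_z), "temperature": (dims3, b.temperature),
            "o2": (dims3, b.o2), "s_lab": (dims3, b.s_lab),
            "s_semi": (dims3, b.s_semi), "dms": (dims3, b.dms),
            "z_ml": (dims2, b.z_ml), "z_eu": (dims2, b.z_eu), "z_dvm": (dims2, b.z_dvm),
            "sst": (dims2, f.sst), "salinity": (dims2, f.salinity),
            "u10": (dims2, f.u10), "f_ice": (dims2, f.f_ice),
            "pressure": (dims2, f.pressure),
            "volume": (dims3, g.volume),
            "region": (dims2, g.region.astype(str)),
            "basin": (dims2, g.basin.astype(str)),
        },
        coords=coords,
        attrs={"seed": world.config.seed, "top_thickness_m": g.top_thickness},
    )
    ds.to_netcdf(path)


def transport_to_triplets(transport: TransportOperator, path, grid: Grid | None = None) -> None:
    """Write the operator as a (row, col, value[y⁻¹]) CSV triplet file.

    With a grid, a JSON sidecar (<path>.json) records the grid metadata
    needed to interpret the flat indices."""
    import json
    from pathlib import Path

    coo = transport.matrix.tocoo()
    pd.DataFrame({"row": coo.row, "col": coo.col, "value_per_year": coo.data}).to_csv(
        path, index=False
    )
    if grid is not None:
        meta = {
            "shape": list(grid.shape),
            "index_order": "depth, lat, lon (C order)",
            "lat": grid.lat.tolist(),
            "lon": grid.lon.tolist(),
            "depth_m": grid.depth.tolist(),
            "top_thickness_m": grid.top_thickness,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def cruises_to_csv(cruises, path) -> None:
    """Write transects in the archive-style layout:
    cruise_id, year, lat, lon, depth_m, ch4_nM, sd_nM."""
    frames = [
        pd.DataFrame(
            {
                "cruise_id": c.cruise_id, "year": c.year, "lat": c.lat,
                "lon": c.lon, "depth_m": c.depth, "ch4_nM": c.ch4, "sd_nM": c.sd,
            }
        )
        for c in cruises
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def cruises_from_csv(path):
    """Read transects from the archive-style CSV written by
    :func:`cruises_to_csv`."""
    from .observations import CruiseTransect

    df = pd.read_csv(path)
    cruises = []
    for cid, sub in df.groupby("cruise_id", sort=False):
        cruises.append(
            CruiseTransect(
                cruise_id=str(cid), year=float(sub["year"].iloc[0]),
                lat=sub["lat"].to_numpy(), lon=sub["lon"].to_numpy(),
                depth=sub["depth_m"].to_numpy(), ch4=sub["ch4_nM"].to_numpy(),
                sd=sub["sd_nM"].to_numpy(),
            )
        )
    return cruises
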