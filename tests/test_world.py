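"""Synthetic world: grid geometry, circulation conservation, field
structure, and cruise sampling."""

import numpy as np
import pytest

from oceanch4.model import solve_steady_state, OxidationParams
from oceanch4.observations import sample_model
from oceanch4.production import ProductionConfig, jprod_po4
from oceanch4.world import (
    EARTH_RADIUS,
    WorldConfig,
    build_world,
    cruises_from_csv,
    cruises_to_csv,
    ideal_age,
    make_circulation,
    make_cruises,
    make_grid,
    transport_to_triplets,
    world_to_netcdf,
)


class TestGrid:
    def test_default_top_thickness(self):
        grid = make_grid(WorldConfig())
        assert grid.top_thickness == pytest.approx(36.14)

    def test_single_layer_degenerate(self):
        grid = make_grid(WorldConfig(nz=1))
        assert grid.nz == 1
        assert np.all(grid.surface_mask_flat())

    def test_total_volume_additivity(self):
        grid = make_grid(WorldConfig())
        expected = 4 * np.pi * EARTH_RADIUS**2 * grid.dz.sum()
        assert grid.volume.sum() == pytest.approx(expected, rel=1e-12)
        assert np.all(grid.volume > 0)
        assert np.all(np.diff(grid.depth) > 0)

    def test_every_column_has_a_basin_and_region(self):
        grid = make_grid(WorldConfig())
        assert set(np.unique(grid.basin)) <= {"Pacific", "Atlantic", "Indian", "Southern"}
        assert set(np.unique(grid.region)) <= {"ANT", "NATL", "TPAC", "STPAC", "TATL", "STATL", "other"}

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_grid(WorldConfig(nlat=1))
        with pytest.raises(ValueError):
            make_grid(WorldConfig(nz=0))


class TestCirculation:
    def test_uniform_tracer_is_invariant(self, world):
        a = world.transport.matrix
        scale = np.abs(a.data).max()
        assert np.abs(a @ np.ones(world.grid.n_cells)).max() < 1e-12 * scale

    def test_volume_weighted_conservation(self, world, rng):
        for _ in range(5):
            c = rng.random(world.grid.n_cells) * 3.0
            assert world.transport.conservation_defect(c) < 1e-10

    def test_zero_strengths_give_zero_operator(self):
        cfg = WorldConfig(overturning_sv=0, gyre_sv=0, kappa_h=0, kappa_v=0, kappa_v_polar=0)
        op = make_circulation(make_grid(cfg), cfg)
        assert op.matrix.nnz == 0 or np.abs(op.matrix.data).max() == 0.0

    def test_ventilation_age_ordering(self, world):
        """Polar sinking ventilates the abyss quickly; gyre interiors are
        reached only via slow downwelling, so their deep water is older."""
        age = ideal_age(world.transport, world.grid)
        assert np.all(age >= -1e-9)
        deep = age[-2]  # ~2-3 km layer
        lat = world.grid.lat
        polar = np.abs(lat) > 70
        gyre = (np.abs(lat) > 20) & (np.abs(lat) < 40)
        assert deep[polar].mean() < deep[gyre].mean()
        # centuries-scale deep ages overall
        assert 100.0 < age.max() < 2000.0


class TestFields:
    def test_functional_fractions_partition_unity(self, world):
        b = world.bio
        has = b.npp > 0
        assert np.allclose((b.f_m + b.f_n + b.f_p)[has], 1.0)

    def test_po4_minimum_in_subtropical_gyre(self, world):
        po4_surf = world.bio.po4[0]
        j, i = np.unravel_index(po4_surf.argmin(), po4_surf.shape)
        assert world.grid.region[j, i] in {"STATL", "STPAC"}
        assert po4_surf.min() < 0.1
        # Southern Ocean maxima
        ant = world.grid.region == "ANT"
        assert po4_surf[ant].mean() > 1.0

    def test_ice_free_outside_polar_rows(self, world):
        lat = world.grid.lat
        nonpolar = np.abs(lat) <= 65.0
        assert np.all(world.forcing.f_ice[nonpolar, :] == 0.0)
        assert world.forcing.f_ice.max() > 0.0

    def test_fields_nonnegative_and_finite(self, world):
        b = world.bio
        for name in ("po4", "npp", "b_z", "o2", "s_lab", "s_semi", "dms"):
            arr = getattr(b, name)
            assert np.all(arr >= 0) and np.all(np.isfinite(arr)), name

    def test_mixed_layer_deep_at_high_latitudes(self, world):
        z_ml = world.bio.z_ml
        lat = world.grid.lat
        assert z_ml[np.abs(lat) > 60].mean() > 5 * z_ml[np.abs(lat) < 35].mean()

    def test_po4_production_pattern_anticorrelates_with_npp(self, world):
        """The geographic fingerprint the pathway discrimination relies on:
        a PO4-inhibited source peaks in the oligotrophic gyres where NPP is
        low, so the two candidate patterns are anti-correlated across the
        low-latitude surface ocean."""
        cfg = ProductionConfig("po4", {"a_0": 1.0, "p_crit": 0.2, "w": 0.218})
        jp = jprod_po4(world.bio, cfg, world.grid)[0]
        lowlat = np.abs(world.grid.lat) < 45.0
        x = jp[lowlat, :].ravel()
        y = world.bio.npp[0][lowlat, :].ravel()
        r = np.corrcoef(x, y)[0, 1]
        assert r < -0.3


class TestCruises:
    @pytest.fixture(scope="class")
    def short_truth(self, world):
        """A cheap truth sequence: preindustrial steady state replicated
        over the cruise years (time structure is irrelevant here)."""
        from oceanch4.forcing import gas_exchange_operator
        from oceanch4.model import ModelState

        gx = gas_exchange_operator(world.forcing, world.grid)
        ox = OxidationParams(k_ox=1 / 172, c_crit=0.33)
        cfg = ProductionConfig("po4", {"a_0": 20.0, "p_crit": 0.2, "w": 0.218})
        jp = jprod_po4(world.bio, cfg, world.grid)
        ss = solve_steady_state(world.transport, gx, jp, ox, world.grid, 706.0)
        return [ModelState(year=y, c=ss.c) for y in (1990.0, 2005.0)]

    def test_noise_free_samples_equal_truth(self, world, short_truth):
        cfg = WorldConfig(noise_sd=0.0)
        cruises = make_cruises(short_truth, world.grid, cfg)
        for c in cruises:
            pred = sample_model(short_truth, c, world.grid)
            assert np.allclose(c.ch4, pred, atol=1e-12)

    def test_every_cruise_reaches_500m(self, world, short_truth):
        cruises = make_cruises(short_truth, world.grid, WorldConfig())
        assert len(cruises) == 11
        assert all(c.max_depth >= 500.0 for c in cruises)

    def test_deterministic_under_seed(self, world, short_truth):
        c1 = make_cruises(short_truth, world.grid, WorldConfig(seed=3))
        c2 = make_cruises(short_truth, world.grid, WorldConfig(seed=3))
        for a, b in zip(c1, c2):
            assert np.array_equal(a.ch4, b.ch4)
        c3 = make_cruises(short_truth, world.grid, WorldConfig(seed=4))
        assert any(not np.array_equal(a.ch4, b.ch4) for a, b in zip(c1, c3))

    def test_cruise_year_outside_span_raises(self, world, short_truth):
        from dataclasses import replace

        cfg = WorldConfig()
        bad_plan = [replace(t, year=1950.0) for t in cfg.cruise_plan]
        with pytest.raises(ValueError):
            make_cruises(short_truth, world.grid, WorldConfig(cruise_plan=bad_plan))


class TestIO:
    def test_world_netcdf_round_trip(self, world, tmp_path):
        import xarray as xr

        p = tmp_path / "world.nc"
        world_to_netcdf(world, p)
        ds = xr.open_dataset(p)
        assert np.allclose(ds["po4"].values, world.bio.po4)
        assert ds.attrs["seed"] == world.config.seed
        ds.close()

    def test_transport_triplets(self, world, tmp_path):
        import pandas as pd
        import scipy.sparse as sp

        p = tmp_path / "transport.csv"
        transport_to_triplets(world.transport, p, grid=world.grid)
        import json

        meta = json.loads((tmp_path / "transport.csv.json").read_text())
        assert meta["shape"] == list(world.grid.shape)
        df = pd.read_csv(p)
        n = world.grid.n_cells
        back = sp.coo_matrix(
            (df["value_per_year"], (df["row"], df["col"])), shape=(n, n)
        ).tocsr()
        diff = (back - world.transport.matrix)
        assert abs(diff).max() < 1e-8 * np.abs(world.transport.matrix.data).max()

    def test_run_netcdf_with_provenance(self, truth_noisy, tmp_path):
        import json

        import xarray as xr

        from oceanch4.pipeline import save_run

        p = tmp_path / "run.nc"
        save_run(truth_noisy.run, truth_noisy.world, p)
        ds = xr.open_dataset(p)
        assert "year" in ds.coords
        assert ds["ch4"].shape[0] == len(truth_noisy.run.states)
        ds.close()
        meta = json.loads((tmp_path / "run.nc.json").read_text())
        assert meta["seed"] == truth_noisy.world.config.seed
        assert meta["pathway"] == "po4"

    def test_cruises_csv_round_trip(self, world, tmp_path, truth_noisy):
        p = tmp_path / "cruises.csv"
        cruises_to_csv(truth_noisy.cruises, p)
        back = cruises_from_csv(p)
        assert len(back) == len(truth_noisy.cruises)
        for a, b in zip(truth_noisy.cruises, back):
            assert a.cruise_id == b.cruise_id
            assert np.allclose(a.ch4, b.ch4)
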