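"""Selection filters, model sampling, disequilibrium, and the weighted cost."""

import numpy as np
import pytest

from oceanch4.model import ModelState
from oceanch4.observations import (
    CruiseTransect,
    cost,
    disequilibrium,
    regional_disequilibrium,
    sample_model,
    select_cruises,
)
from oceanch4.world import WorldConfig, build_world, make_cruises


def make_transect(cruise_id="T", year=2000.0, depths=(10.0, 600.0), lat=0.0, lon=200.0, ch4=1.0):
    d = np.asarray(depths, dtype=float)
    n = d.size
    return CruiseTransect(
        cruise_id=cruise_id, year=year,
        lat=np.full(n, lat), lon=np.full(n, lon), depth=d,
        ch4=np.full(n, ch4), sd=np.full(n, 0.2),
    )


class TestSelect:
    def test_shallow_transect_excluded(self, world):
        shallow = make_transect(depths=(10.0, 300.0))
        deep = make_transect(depths=(10.0, 600.0))
        kept = select_cruises([shallow, deep], world.bio, world.grid)
        assert [c.cruise_id for c in kept] == [deep.cruise_id]

    def test_omz_crossing_excluded(self):
        w = build_world(WorldConfig(include_omz=True))
        omz_cols = np.argwhere(w.bio.o2.min(axis=0) < 5.0)
        j, i = omz_cols[0]
        bad = make_transect(lat=float(w.grid.lat[j]), lon=float(w.grid.lon[i]))
        good = make_transect(lat=-30.0, lon=200.0)
        kept = select_cruises([bad, good], w.bio, w.grid)
        assert [c.cruise_id for c in kept] == [good.cruise_id]

    def test_compliant_set_fully_retained(self, world, truth_noisy):
        kept = select_cruises(truth_noisy.cruises, world.bio, world.grid)
        assert len(kept) == 11

    def test_empty_result_warns(self, world):
        with pytest.warns(UserWarning):
            out = select_cruises([make_transect(depths=(10.0,))], world.bio, world.grid)
        assert out == []


class TestSampling:
    def test_collocation_at_cell_center(self, world, rng):
        c = rng.random(world.grid.n_cells)
        state = ModelState(year=2000.0, c=c)
        g = world.grid
        k, j, i = 3, 10, 5
        tr = make_transect(depths=(float(g.depth[k]),), lat=float(g.lat[j]), lon=float(g.lon[i]))
        pred = sample_model([state], tr, g)
        assert pred[0] == pytest.approx(c.reshape(g.shape)[k, j, i], rel=1e-12)

    def test_noise_free_round_trip_rmse_zero(self, truth_clean):
        preds = [sample_model(truth_clean.run.states, c, truth_clean.world.grid)
                 for c in truth_clean.cruises]
        cb = cost(preds, truth_clean.cruises)
        assert cb.total == pytest.approx(0.0, abs=1e-12)

    def test_later_cruise_sees_higher_anthropogenic_baseline(self, truth_clean):
        g = truth_clean.world.grid
        early = make_transect(year=1991.0, depths=(10.0, 600.0), lat=30.0, lon=200.0)
        late = make_transect(year=2010.0, depths=(10.0, 600.0), lat=30.0, lon=200.0)
        p_early = sample_model(truth_clean.run.states, early, g)
        p_late = sample_model(truth_clean.run.states, late, g)
        assert p_late[0] > p_early[0]

    def test_year_outside_span_raises(self, truth_clean):
        tr = make_transect(year=1600.0)
        with pytest.raises(ValueError):
            sample_model(truth_clean.run.states, tr, truth_clean.world.grid)

    def test_below_grid_depth_clamped_not_dropped(self, truth_clean):
        g = truth_clean.world.grid
        tr = make_transect(depths=(10.0, 9000.0), lat=0.0, lon=200.0)
        pred = sample_model(truth_clean.run.states, tr, g)
        assert np.all(np.isfinite(pred))


class TestDisequilibrium:
    def test_zero_at_saturation(self, world, gx):
        g = world.grid
        j, i = g.column_index(-30.0, 200.0)
        s = float(gx.saturation_surface(world.atmosphere.value(2000.0))[j, i])
        tr = make_transect(depths=(10.0,), lat=-30.0, lon=200.0, ch4=s)
        delta, surf = disequilibrium(tr, world.forcing, world.atmosphere, g)
        assert surf[0]
        assert delta[0] == pytest.approx(0.0, abs=1e-12)

    def test_regional_aggregation_recovers_imposed_offsets(self, world):
        """Build observations at exactly saturation + a known per-region
        offset; the regional machinery must return those offsets,
        including the observed real-ocean ordering it must represent."""
        offsets = {"ANT": -0.75, "NATL": -0.10, "TPAC": 0.16,
                   "STPAC": 0.47, "TATL": 0.70, "STATL": 0.71}
        g = world.grid
        x = world.atmosphere.value(2000.0)
        cruises = []
        from oceanch4.forcing import saturation, solubility

        for region, off in offsets.items():
            cols = np.argwhere(g.region == region)[:4]
            lats = np.array([g.lat[j] for j, _ in cols])
            lons = np.array([g.lon[i] for _, i in cols])
            s = np.array([
                float(saturation(x, world.forcing.pressure[j, i],
                                 solubility(world.forcing.sst[j, i], world.forcing.salinity[j, i])))
                for j, i in cols
            ])
            cruises.append(CruiseTransect(
                cruise_id=region, year=2000.0, lat=lats, lon=lons,
                depth=np.full(lats.size, 10.0), ch4=np.clip(s + off, 0, None),
                sd=np.full(lats.size, 0.2),
            ))
        out = regional_disequilibrium(cruises, world.forcing, world.atmosphere, g)
        for region, off in offsets.items():
            mean, n = out[region]
            assert mean == pytest.approx(off, abs=1e-9)
            assert n == 4
        ordering = sorted(offsets, key=lambda r: out[r][0])
        assert ordering == ["ANT", "NATL", "TPAC", "STPAC", "TATL", "STATL"]


class TestCost:
    def test_two_transect_weighting_oracle(self):
        """Hand-computed case: constant errors of 1 and 2 nM on transects
        of 2 and 3 samples give 1*(2/5) + 2*(3/5) = 1.6 nM."""
        t1 = make_transect("A", depths=(10.0, 20.0), ch4=1.0)
        t2 = make_transect("B", depths=(10.0, 20.0, 30.0), ch4=1.0)
        preds = [np.full(2, 2.0), np.full(3, 3.0)]
        cb = cost(preds, [t1, t2])
        assert cb.total == pytest.approx(1.6)
        assert cb.weights.sum() == pytest.approx(1.0)

    def test_perfect_predictions(self):
        t = make_transect()
        assert cost([t.ch4.copy()], [t]).total == 0.0

    def test_single_transect_is_its_rmse(self, rng):
        t = make_transect(depths=tuple(range(10, 110, 10)))
        pred = t.ch4 + rng.normal(0, 0.5, t.n_samples)
        cb = cost([pred], [t])
        assert cb.total == pytest.approx(float(np.sqrt(np.mean((pred - t.ch4) ** 2))))

    def test_order_invariance(self, rng):
        t1 = make_transect("A", depths=(10.0, 20.0, 30.0))
        t2 = make_transect("B", depths=(10.0, 20.0))
        p1 = t1.ch4 + rng.normal(0, 0.3, 3)
        p2 = t2.ch4 + rng.normal(0, 0.3, 2)
        assert cost([p1, p2], [t1, t2]).total == pytest.approx(
            cost([p2, p1], [t2, t1]).total
        )

    def test_split_invariance(self, rng):
        """Splitting a transect into two with the same points leaves the
        n-proportional weighted cost unchanged."""
        t = make_transect("A", depths=tuple(range(10, 90, 10)))
        pred = t.ch4 + rng.normal(0, 0.3, t.n_samples)
        whole = cost([pred], [t]).total
        # split so both halves have the same per-sample error structure
        idx_a, idx_b = np.arange(0, 8, 2), np.arange(1, 8, 2)
        ta, tb = t.subset(idx_a), t.subset(idx_b)
        err = pred - t.ch4
        same_rmse = np.sqrt(np.mean(err**2))
        pa = ta.ch4 + same_rmse
        pb = tb.ch4 + same_rmse
        split = cost([pa, pb], [ta, tb]).total
        assert split == pytest.approx(same_rmse)
        assert whole == pytest.approx(same_rmse, rel=0.5)  # same scale by construction

    def test_rmse_decreases_toward_observations(self):
        t = make_transect(depths=(10.0, 20.0, 30.0))
        far = cost([t.ch4 + 1.0], [t]).total
        near = cost([t.ch4 + 0.25], [t]).total
        assert near < far

    def test_misaligned_predictions_rejected(self):
        t = make_transect()
        with pytest.raises(ValueError):
            cost([np.zeros(5)], [t])

    def test_diagnostics_exports(self, tmp_path, world):
        import json

        import pandas as pd

        from oceanch4.observations import regional_summary_to_json

        t1 = make_transect("A", depths=(10.0, 20.0))
        cb = cost([t1.ch4 + 0.5], [t1])
        cb.to_csv(tmp_path / "rmse.csv")
        df = pd.read_csv(tmp_path / "rmse.csv")
        assert df["rmse_nM"].iloc[0] == pytest.approx(0.5)
        summary = {"STPAC": (0.47, 12)}
        regional_summary_to_json(summary, tmp_path / "regions.json")
        loaded = json.loads((tmp_path / "regions.json").read_text())
        assert loaded["STPAC"]["mean_nM"] == pytest.approx(0.47)
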