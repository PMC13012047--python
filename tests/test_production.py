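"""Production parameterizations: anchor points, bounds, monotonicity,
depth confinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oceanch4.production import (
    BioFields,
    ProductionConfig,
    jprod_combined,
    jprod_npp,
    jprod_po4,
    jprod_substrate,
    jprod_zoo,
    production_rate,
    substrate_threshold,
)


def scaled_fields(world, **overrides) -> BioFields:
    b = world.bio
    kw = {f: getattr(b, f).copy() for f in (
        "po4", "npp", "f_m", "f_n", "f_p", "b_z", "temperature", "o2",
        "s_lab", "s_semi", "dms", "z_ml", "z_eu", "z_dvm")}
    kw.update(overrides)
    return BioFields(**kw)


class TestConfigValidation:
    def test_unknown_pathway(self):
        with pytest.raises(ValueError):
            ProductionConfig("magic", {})

    def test_wrong_parameter_set(self):
        with pytest.raises(ValueError):
            ProductionConfig("po4", {"a_0": 1.0})

    @pytest.mark.parametrize(
        "pathway,params",
        [
            ("po4", {"a_0": 1.0, "p_crit": 0.2, "w": 0.0}),
            ("po4", {"a_0": -1.0, "p_crit": 0.2, "w": 0.1}),
            ("zoo", {"a_zoo": 1.0, "q10": 0.5, "k_o2": 5.0}),
            ("labile", {"a_s": 1.0, "k_s": 1.0, "b_s": 1.0}),
        ],
    )
    def test_bad_parameter_values(self, pathway, params):
        with pytest.raises(ValueError):
            ProductionConfig(pathway, params)


class TestNpp:
    def test_zero_yields_zero_field(self, world):
        cfg = ProductionConfig("npp", {"a_m": 0.0, "a_n": 0.0, "a_p": 0.0})
        assert np.all(jprod_npp(world.bio, cfg, world.grid) == 0.0)

    def test_picoplankton_only_weights_subtropics(self, world):
        """With yield assigned only to picoplankton, production follows the
        pico fraction that dominates oligotrophic gyres."""
        cfg = ProductionConfig("npp", {"a_m": 0.0, "a_n": 0.0, "a_p": 1.0})
        jp = jprod_npp(world.bio, cfg, world.grid)
        assert np.allclose(jp, np.where(
            world.grid.depth[:, None, None] < world.bio.z_eu,
            world.bio.f_p * world.bio.npp, 0.0))
        surf = jp[0]
        gyre = np.isin(world.grid.region, ["STPAC", "STATL"])
        polar = np.isin(world.grid.region, ["ANT"])
        # per unit NPP, gyres out-yield polar waters
        assert (surf[gyre] / world.bio.npp[0][gyre]).mean() > \
               (surf[polar] / world.bio.npp[0][polar]).mean()

    def test_zero_below_euphotic_depth(self, world):
        cfg = ProductionConfig("npp", {"a_m": 1.0, "a_n": 1.0, "a_p": 1.0})
        jp = jprod_npp(world.bio, cfg, world.grid)
        below = world.grid.depth[:, None, None] >= world.bio.z_eu[None]
        assert np.all(jp[below] == 0.0)


class TestZoo:
    def test_reference_temperature_anchor(self, world):
        cfg = ProductionConfig("zoo", {"a_zoo": 2.0, "q10": 3.0, "k_o2": 20.0})
        fields = scaled_fields(world, temperature=np.full(world.grid.shape, 20.0))
        jp = jprod_zoo(fields, cfg, world.grid)
        expected = 2.0 * fields.b_z * fields.o2 / (fields.o2 + 20.0)
        mask = world.grid.depth[:, None, None] < fields.z_dvm
        assert np.allclose(jp[mask], expected[mask])

    def test_half_saturation_anchor(self, world):
        cfg = ProductionConfig("zoo", {"a_zoo": 1.0, "q10": 1.0, "k_o2": 50.0})
        fields = scaled_fields(world, o2=np.full(world.grid.shape, 50.0),
                               temperature=np.full(world.grid.shape, 20.0))
        jp = jprod_zoo(fields, cfg, world.grid)
        mask = world.grid.depth[:, None, None] < fields.z_dvm
        assert np.allclose(jp[mask], 0.5 * fields.b_z[mask])

    def test_q10_of_4_quadruples_rate_at_30C(self, world):
        base = ProductionConfig("zoo", {"a_zoo": 1.0, "q10": 4.0, "k_o2": 20.0})
        f20 = scaled_fields(world, temperature=np.full(world.grid.shape, 20.0))
        f30 = scaled_fields(world, temperature=np.full(world.grid.shape, 30.0))
        jp20 = jprod_zoo(f20, base, world.grid)
        jp30 = jprod_zoo(f30, base, world.grid)
        nz = jp20 > 0
        assert np.allclose(jp30[nz] / jp20[nz], 4.0)


class TestSubstrate:
    def test_break_even_concentration_is_exact_zero(self, world):
        a_s, k_s, b_s = 10.0, 4.0, 0.3
        s_star = substrate_threshold(k_s, b_s)
        cfg = ProductionConfig("semilabile", {"a_s": a_s, "k_s": k_s, "b_s": b_s})
        fields = scaled_fields(world, s_semi=np.full(world.grid.shape, s_star))
        assert np.all(jprod_substrate(fields, cfg, world.grid) == 0.0)
        below = scaled_fields(world, s_semi=np.full(world.grid.shape, 0.5 * s_star))
        assert np.all(jprod_substrate(below, cfg, world.grid) == 0.0)

    def test_saturating_limit(self, world):
        cfg = ProductionConfig("labile", {"a_s": 7.0, "k_s": 1.0, "b_s": 0.0})
        fields = scaled_fields(world, s_lab=np.full(world.grid.shape, 1e9))
        jp = jprod_substrate(fields, cfg, world.grid)
        mask = world.grid.depth[:, None, None] < fields.z_ml
        assert np.allclose(jp[mask], 7.0, rtol=1e-6)

    @given(b_s=st.floats(0.0, 0.95))
    @settings(max_examples=40, deadline=None)
    def test_rate_nondecreasing_in_substrate(self, b_s):
        """Brute-force oracle: f*max(0, f-b) is nondecreasing over f in
        [0, 1) for every valid threshold fraction."""
        f = np.linspace(0.0, 0.999, 2000)
        rate = f * np.maximum(0.0, f - b_s)
        assert np.all(np.diff(rate) >= -1e-15)


class TestPo4:
    def test_midpoint_gives_half_maximum(self, world):
        cfg = ProductionConfig("po4", {"a_0": 20.0, "p_crit": 0.4, "w": 0.1})
        fields = scaled_fields(world, po4=np.full(world.grid.shape, 0.4))
        jp = jprod_po4(fields, cfg, world.grid)
        mask = world.grid.depth[:, None, None] < fields.z_ml
        assert np.allclose(jp[mask], 10.0)

    def test_vanishes_at_high_po4(self, world):
        cfg = ProductionConfig("po4", {"a_0": 20.0, "p_crit": 0.2, "w": 0.218})
        fields = scaled_fields(world, po4=np.full(world.grid.shape, 50.0))
        assert np.all(jprod_po4(fields, cfg, world.grid) < 1e-10)

    @given(
        a_0=st.floats(0.1, 100.0),
        p_crit=st.floats(0.01, 1.0),
        w=st.floats(0.01, 1.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_strictly_decreasing_and_bounded(self, a_0, p_crit, w):
        po4 = np.linspace(0.0, 3.0, 500)
        rate = a_0 * (0.5 - 0.5 * np.tanh((po4 - p_crit) / w))
        assert np.all(np.diff(rate) <= 0)
        assert np.all((rate >= 0) & (rate <= a_0))
        # strict decrease wherever the tanh has not saturated in floats
        interior = (rate > 1e-12 * a_0) & (rate < a_0 * (1 - 1e-12))
        idx = np.nonzero(interior[:-1] & interior[1:])[0]
        assert np.all(np.diff(rate)[idx] < 0)


class TestCombined:
    def test_saturated_substrate_reduces_to_po4(self, world):
        pp = {"a_0": 15.0, "p_crit": 0.2, "w": 0.2}
        combo = ProductionConfig("po4_semilabile", {**pp, "k_s": 2.0})
        fields = scaled_fields(world, s_semi=np.full(world.grid.shape, 1e12))
        jp_combo = jprod_combined(fields, combo, world.grid)
        jp_po4 = jprod_po4(fields, ProductionConfig("po4", pp), world.grid)
        assert np.allclose(jp_combo, jp_po4, rtol=1e-9)

    def test_additive_variant_reduces_to_po4(self, world):
        pp = {"a_0": 15.0, "p_crit": 0.2, "w": 0.2}
        combo = ProductionConfig(
            "npp_plus_po4", {**pp, "a_m": 0.0, "a_n": 0.0, "a_p": 0.0}
        )
        jp_combo = jprod_combined(world.bio, combo, world.grid)
        jp_po4 = jprod_po4(world.bio, ProductionConfig("po4", pp), world.grid)
        assert np.array_equal(jp_combo, jp_po4)

    def test_limitation_factor_never_exceeds_po4_rate(self, world, rng):
        pp = {"a_0": 15.0, "p_crit": 0.2, "w": 0.2}
        for _ in range(5):
            s = rng.random(world.grid.shape) * 20.0
            fields = scaled_fields(world, s_semi=s)
            jp_combo = jprod_combined(
                fields, ProductionConfig("po4_semilabile", {**pp, "k_s": 3.0}), world.grid
            )
            jp_po4 = jprod_po4(fields, ProductionConfig("po4", pp), world.grid)
            assert np.all(jp_combo <= jp_po4 + 1e-12)


class TestInvariants:
    @pytest.mark.parametrize(
        "pathway,params,horizon",
        [
            ("npp", {"a_m": 0.5, "a_n": 0.5, "a_p": 0.5}, "z_eu"),
            ("zoo", {"a_zoo": 1.0, "q10": 2.0, "k_o2": 30.0}, "z_dvm"),
            ("dms", {"a_s": 5.0, "k_s": 2.0, "b_s": 0.1}, "z_ml"),
            ("labile", {"a_s": 5.0, "k_s": 2.0, "b_s": 0.1}, "z_ml"),
            ("semilabile", {"a_s": 5.0, "k_s": 2.0, "b_s": 0.1}, "z_ml"),
            ("po4", {"a_0": 20.0, "p_crit": 0.2, "w": 0.2}, "z_ml"),
        ],
    )
    def test_depth_confinement_and_nonnegativity(self, world, pathway, params, horizon):
        cfg = ProductionConfig(pathway, params)
        jp = production_rate(world.bio, cfg, world.grid)
        below = world.grid.depth[:, None, None] >= getattr(world.bio, horizon)[None]
        assert np.all(jp[below] == 0.0)
        assert np.all(jp >= 0.0)

    def test_none_pathway_is_zero(self, world):
        assert np.all(production_rate(world.bio, ProductionConfig("none", {}), world.grid) == 0.0)

    def test_pathway_specific_maxima(self, world):
        po4 = ProductionConfig("po4", {"a_0": 20.0, "p_crit": 0.2, "w": 0.2})
        assert production_rate(world.bio, po4, world.grid).max() <= 20.0
        sub = ProductionConfig("labile", {"a_s": 5.0, "k_s": 2.0, "b_s": 0.3})
        assert production_rate(world.bio, sub, world.grid).max() <= 5.0 * (1 - 0.3)
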