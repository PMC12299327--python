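"""Entropy-weighted nutrition index, AIC trendline selection, cultivation zoning."""
import numpy as np
import pandas as pd
import pytest

import ferncast as fc
from ferncast.containers import SuitabilityMap
from ferncast.cultivation import ZONE_CODES, classify_zones, zone_table
from ferncast.synthetic import fixture_geometry, masks_from_areas


class TestStandardize:
    def test_min_max_arithmetic(self):
        out = fc.standardize(pd.DataFrame({"x": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(out["x"], [0.0, 0.5, 1.0])

    def test_spanning_column_unchanged(self):
        x = pd.DataFrame({"x": [0.0, 0.3, 1.0]})
        assert fc.standardize(x).equals(x.astype(float))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        a = fc.standardize(pd.DataFrame({"x": x}))
        b = fc.standardize(pd.DataFrame({"x": 3.0 * x - 7.0}))
        np.testing.assert_allclose(a["x"], b["x"], atol=1e-12)

    def test_constant_column_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = fc.standardize(pd.DataFrame({"x": [5.0, 5.0, 5.0]}))
        assert (out["x"] == 0).all()


class TestEntropyWeights:
    def test_hand_example(self):
        """[[1,1],[1,3]]: constant column weight 0, varying column weight 1."""
        w = fc.entropy_weights(pd.DataFrame([[1.0, 1.0], [1.0, 3.0]]))
        np.testing.assert_allclose(w.to_numpy(), [0.0, 1.0], atol=1e-9)

    def test_identical_columns_share_weight(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 30)
        w = fc.entropy_weights(pd.DataFrame({"a": x, "b": x}))
        np.testing.assert_allclose(w.to_numpy(), [0.5, 0.5])

    def test_weights_sum_to_one_nonnegative(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            X = np.random.default_rng(seed).uniform(0, 1, (20, 4))
            w = fc.entropy_weights(pd.DataFrame(X))
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(0, 1, (25, 4)), columns=list("abcd"))
        w1 = fc.entropy_weights(df)
        w2 = fc.entropy_weights(df[list("dcba")])
        for c in "abcd":
            assert w1[c] == pytest.approx(w2[c])

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            fc.entropy_weights(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestNutritionIndex:
    def test_full_scores_give_unit_index(self):
        X = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        w = pd.Series([0.25] * 4, index=list("abcd"))
        np.testing.assert_allclose(fc.nutrition_index(X, w), 1.0)

    def test_degenerate_weight_selects_column(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(0, 1, (10, 4)), columns=list("abcd"))
        w = pd.Series([1.0, 0, 0, 0], index=list("abcd"))
        np.testing.assert_allclose(fc.nutrition_index(X, w), X["a"])

    def test_dot_product_example(self):
        X = pd.DataFrame([[0.2, 0.4, 0.6, 0.8]], columns=list("abcd"))
        w = pd.Series([0.25] * 4, index=list("abcd"))
        assert fc.nutrition_index(X, w)[0] == pytest.approx(0.5)


class TestSiteProductivity:
    def test_zero_inputs(self):
        assert fc.site_productivity(np.r_[0.0], np.r_[0.0])[0] == 0.0

    def test_rescaled_mean(self):
        assert fc.site_productivity(np.r_[0.6], np.r_[0.5])[0] == pytest.approx(0.55)

    def test_raw_sum_mode(self):
        assert fc.site_productivity(np.r_[0.6], np.r_[0.5], rescale=False)[0] == pytest.approx(1.1)

    def test_monotone_in_each_argument(self):
        S = np.linspace(0, 1, 10)
        P = fc.site_productivity(S, np.full(10, 0.5))
        assert np.all(np.diff(P) > 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fc.site_productivity(np.r_[0.1, 0.2], np.r_[0.1])


class TestModelSelection:
    def test_linear_truth_recovered_across_seeds(self):
        """P = 0.3 + 0.5 S + noise: linear wins in >= 9/10 seeds, slope in [0.4, 0.6]."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            S = rng.uniform(0.05, 0.95, 36)
            P = 0.3 + 0.5 * S + rng.normal(0, 0.02, 36)
            m = fc.fit_productivity_model(S, P)
            if m.selected_ == "line2P":
                wins += 1
                assert 0.4 <= m.params_[0] <= 0.6
        assert wins >= 9

    def test_exact_linear_data_selects_linear(self):
        S = np.linspace(0.1, 0.9, 20)
        m = fc.fit_productivity_model(S, 0.2 + 0.7 * S)
        assert m.selected_ == "line2P"
        assert m.aic_table_.set_index("form").loc["line2P", "rss"] < 1e-12

    def test_null_relation_has_no_significant_slope(self):
        rng = np.random.default_rng(5)
        S = rng.uniform(0.1, 0.9, 36)
        P = rng.normal(0.5, 0.05, 36)  # independent of S
        m = fc.fit_productivity_model(S, P)
        lo, hi = m.slope_ci_
        assert lo <= 0 <= hi

    def test_selected_aic_within_tie_band_and_parsimonious(self):
        rng = np.random.default_rng(6)
        S = rng.uniform(0.1, 0.9, 36)
        P = 0.3 + 0.5 * S + rng.normal(0, 0.02, 36)
        m = fc.fit_productivity_model(S, P)
        tab = m.aic_table_[np.isfinite(m.aic_table_["aic"])]
        best = tab["aic"].min()
        sel = tab[tab["form"] == m.selected_].iloc[0]
        assert sel["aic"] - best < 2.0
        tied = tab[tab["aic"] - best < 2.0]
        assert sel["k"] == tied["k"].min()

    def test_nonpositive_s_skips_log_and_power(self):
        S = np.linspace(-0.2, 0.9, 20)
        m = fc.fit_productivity_model(S, 0.2 + 0.7 * S)
        tab = m.aic_table_.set_index("form")
        for form in ("log2P", "power2P", "power3P"):
            assert tab.loc[form, "skipped"] != ""

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            fc.fit_productivity_model(np.r_[0.1, 0.2, 0.3], np.r_[0.1, 0.2, 0.3])


class TestZoning:
    def test_threshold_conventions(self):
        suitable = np.ones((1, 3), dtype=bool)
        P = np.array([[0.60, 0.58, 0.36]])
        z = classify_zones(P, suitable)
        assert z[0, 0] == ZONE_CODES["core"]  # P > 0.58
        assert z[0, 1] == ZONE_CODES["general"]  # boundary belongs to general
        assert z[0, 2] == ZONE_CODES["marginal"]

    def test_unsuitable_cells_carry_no_zone(self):
        P = np.full((2, 2), 0.9)
        z = classify_zones(P, np.zeros((2, 2), dtype=bool))
        assert (z == 0).all()

    def test_identity_model_matches_brute_force_rebinning(self):
        """With P = S, zones are a deterministic re-binning of the S raster."""
        geom = fixture_geometry(0.2)
        rng = np.random.default_rng(7)
        S = rng.uniform(0, 1, geom.shape)
        smap = SuitabilityMap(geom, S, cutoff=0.2)
        ident = fc.fit_productivity_model(np.linspace(0.01, 0.99, 20), np.linspace(0.01, 0.99, 20))
        assert ident.selected_ == "line2P"
        zm = fc.project_zones(ident, smap, fc.cell_areas(geom))
        suit = S >= 0.2
        assert ((zm.zones == 3) == (suit & (S > 0.58))).all()
        assert ((zm.zones == 2) == (suit & (S >= 0.37) & (S <= 0.58))).all()
        assert ((zm.zones == 1) == (suit & (S < 0.37))).all()

    def test_zone_areas_partition_suitable_area(self):
        geom = fixture_geometry(0.1)
        rng = np.random.default_rng(8)
        S = rng.uniform(0, 1, geom.shape)
        smap = SuitabilityMap(geom, S, cutoff=0.3)
        areas = fc.cell_areas(geom)
        ident = fc.fit_productivity_model(np.linspace(0.01, 0.99, 20), np.linspace(0.01, 0.99, 20))
        zm = fc.project_zones(ident, smap, areas)
        suitable_total = areas[smap.suitable].sum() / 1e4
        assert zm.total == pytest.approx(suitable_total, abs=1e-9)

    def test_fixture_reproduces_published_partition(self):
        """Marginal 3.20 + general 2.68 + core 0.24 = 6.12 total."""
        geom = fixture_geometry()
        m_marg, m_gen, m_core = masks_from_areas(geom, [3.20, 2.68, 0.24])
        S = np.zeros(geom.shape)
        S[m_marg] = 0.30
        S[m_gen] = 0.50
        S[m_core] = 0.70
        smap = SuitabilityMap(geom, S, cutoff=0.25)
        areas = fc.cell_areas(geom)
        ident = fc.fit_productivity_model(np.linspace(0.01, 0.99, 20), np.linspace(0.01, 0.99, 20))
        zm = fc.project_zones(ident, smap, areas)
        assert zm.areas["marginal"] == pytest.approx(3.20, abs=0.01)
        assert zm.areas["general"] == pytest.approx(2.68, abs=0.01)
        assert zm.areas["core"] == pytest.approx(0.24, abs=0.01)
        assert zm.total == pytest.approx(6.12, abs=0.02)
        assert zm.total == pytest.approx(sum(zm.areas.values()), abs=1e-12)

    def test_positive_slope_never_demotes_zone_when_s_rises(self):
        """End-to-end monotonicity of the zone map in S."""
        geom = fixture_geometry(0.2)
        S = np.sort(np.random.default_rng(9).uniform(0, 1, geom.shape), axis=None).reshape(geom.shape)
        smap = SuitabilityMap(geom, S, cutoff=0.1)
        rng = np.random.default_rng(10)
        Sf = rng.uniform(0.05, 0.95, 36)
        m = fc.fit_productivity_model(Sf, 0.3 + 0.5 * Sf + rng.normal(0, 0.02, 36))
        assert m.slope_ > 0
        zm = fc.project_zones(m, smap, fc.cell_areas(geom))
        flat = zm.zones.ravel()[smap.suitable.ravel()]
        assert np.all(np.diff(flat.astype(int)) >= 0)  # S ascending => zone non-decreasing
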