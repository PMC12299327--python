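"""Ensemble SDM: thinning, pseudo-absences, splits, learners, skill, ensemble."""
import numpy as np
import pytest

import ferncast as fc
from ferncast.containers import GridGeometry, SuitabilityMap, tier_classify
from ferncast.sdm import (
    EnsembleMember,
    EnvelopeModel,
    EvaluationScore,
    binarize_and_tier,
    fit_base_model,
    max_tss_threshold,
    member_scores,
    model_registry,
)


class TestThinning:
    def test_points_in_same_km_cell_collapse(self):
        occ = fc.OccurrenceSet([102.0, 102.0005], [31.0, 31.0005])  # ~70 m apart
        assert len(fc.thin_occurrences(occ)) == 1

    def test_distant_points_survive(self):
        occ = fc.OccurrenceSet([102.0, 102.1], [31.0, 31.0])  # ~9.5 km apart
        assert len(fc.thin_occurrences(occ)) == 2

    def test_256_raw_with_80_duplicate_pairs_thin_to_176(self):
        """256 raw points built with 80 same-cell duplicates leave 176 survivors."""
        rng = np.random.default_rng(0)
        # 176 points on distinct km cells (a coarse lattice guarantees separation)
        base_lon = 100.0 + 0.05 * np.arange(16)
        base_lat = 30.0 + 0.05 * np.arange(11)
        lon, lat = np.meshgrid(base_lon, base_lat)
        lon, lat = lon.ravel()[:176], lat.ravel()[:176]
        dup_lon = lon[:80] + 1e-4  # ~10 m offsets stay in the same km cell
        dup_lat = lat[:80] + 1e-4
        order = rng.permutation(256)
        occ = fc.OccurrenceSet(
            np.concatenate([lon, dup_lon])[order], np.concatenate([lat, dup_lat])[order]
        )
        assert len(occ) == 256
        assert len(fc.thin_occurrences(occ)) == 176

    def test_empty_in_empty_out(self):
        occ = fc.OccurrenceSet(np.array([]), np.array([]))
        assert len(fc.thin_occurrences(occ)) == 0


class TestPseudoAbsences:
    def test_count_exclusion_and_determinism(self, small_landscape, presence_absence):
        _, stack, _ = small_landscape
        pres = fc.OccurrenceSet(
            presence_absence[0].lon[presence_absence[0].is_presence],
            presence_absence[0].lat[presence_absence[0].is_presence],
        )
        pa1 = fc.sample_pseudo_absences(stack, pres, 1200, seed=3)
        pa2 = fc.sample_pseudo_absences(stack, pres, 1200, seed=3)
        assert len(pa1) == 1200
        assert np.array_equal(pa1.lon, pa2.lon)
        pi = set(zip(*stack.geometry.index_of(pres.lon, pres.lat)))
        ai = set(zip(*stack.geometry.index_of(pa1.lon, pa1.lat)))
        assert not pi & ai

    def test_exhaustive_draw_returns_every_free_cell(self):
        lc = fc.LandscapeConfig(grid_rows=10, grid_cols=10, n_vars=3, seed=1)
        stack = fc.generate_env_stack(lc)
        pres = fc.OccurrenceSet([stack.geometry.lon[0]], [stack.geometry.lat[0]])
        pa = fc.sample_pseudo_absences(stack, pres, 99, seed=0)
        assert len(pa) == 99

    def test_shortfall_is_named(self):
        lc = fc.LandscapeConfig(grid_rows=10, grid_cols=10, n_vars=3, seed=1)
        stack = fc.generate_env_stack(lc)
        pres = fc.OccurrenceSet([stack.geometry.lon[0]], [stack.geometry.lat[0]])
        with pytest.raises(ValueError, match="99"):
            fc.sample_pseudo_absences(stack, pres, 100, seed=0)


class TestSplits:
    def test_train_fraction_preserves_class_counts(self):
        y = np.r_[np.ones(176), np.zeros(1200)]
        splits = fc.split_repeats(y, train_frac=0.75, repeats=10, seed=0)
        assert len(splits) == 10
        for tr, te in splits:
            assert y[tr].sum() == 132  # 176 * 0.75
            assert np.intersect1d(tr, te).size == 0
            assert np.union1d(tr, te).size == y.size

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            fc.split_repeats(np.r_[0, 1], train_frac=1.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fc.split_repeats(np.ones(10))


class TestBaseModels:
    def test_all_algorithms_separate_separable_data(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-3, 0.3, (50, 2)), rng.normal(3, 0.3, (50, 2))])
        y = np.r_[np.zeros(50), np.ones(50)]
        for alg in model_registry():
            model = fit_base_model(alg, X, y, seed=0)
            assert fc.evaluate(member_scores(model, X), y).roc_auc == 1.0

    def test_envelope_scores_box_membership(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (100, 2))
        y = np.ones(100)
        env = EnvelopeModel(quantile=0.0).fit(X, y)
        inside = np.array([[0.5, 0.5]])
        outside = np.array([[2.0, 0.5]])
        assert member_scores(env, inside)[0] == 1.0
        assert member_scores(env, outside)[0] == 0.0

    def test_label_shuffle_gives_chance_auc(self):
        """Cross-validated AUC on label-shuffled data is ~0.5."""
        from sklearn.model_selection import cross_val_score

        rng = np.random.default_rng(6)
        X = rng.normal(size=(600, 4))
        y = rng.permutation(np.r_[np.zeros(300), np.ones(300)])
        auc = cross_val_score(model_registry()["glm"], X, y, cv=5, scoring="roc_auc").mean()
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_unknown_algorithm_lists_registry(self):
        with pytest.raises(ValueError, match="registry"):
            fit_base_model("cnn", np.zeros((4, 2)), np.r_[0, 1, 0, 1])


class TestEvaluate:
    def test_perfect_scorer(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        s = y.astype(float)
        ev = fc.evaluate(s, y)
        assert (ev.roc_auc, ev.tss, ev.kappa) == (1.0, 1.0, 1.0)

    def test_hand_confusion_table(self):
        """TP=40 FN=10 TN=45 FP=5: sens .8, spec .9 -> TSS .70; kappa .70."""
        tss, kappa = fc.confusion_skill(40, 10, 45, 5)
        assert tss == pytest.approx(0.70)
        assert kappa == pytest.approx(0.70)

    def test_constant_scorer_is_uninformative(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        ev = fc.evaluate(np.full(20, 0.4), y)
        assert ev.roc_auc == 0.5
        assert ev.tss == pytest.approx(0.0)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.uniform(0.01, 0.99, 200) * (1 + 0.5 * y)
        a = fc.evaluate(s, y).roc_auc
        b = fc.evaluate(np.log(s / (1 - np.clip(s, 0, 0.999))), y).roc_auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fc.evaluate(np.r_[0.1, 0.9], np.r_[1, 1])


class TestEnsemble:
    def _member(self, tss):
        score = EvaluationScore(roc_auc=0.9, tss=tss, kappa=0.8, threshold_at_max_tss=0.5)
        return EnsembleMember("glm", 0, score, model=None)

    def test_gate_drops_weak_members(self):
        members = [self._member(0.9), self._member(0.6)]
        passing, w = fc.build_ensemble(members, tss_min=0.7)
        assert len(passing) == 1 and passing[0].score.tss == 0.9
        assert w[0] == 1.0

    def test_weights_proportional_to_tss(self):
        passing, w = fc.build_ensemble([self._member(0.9), self._member(0.6)], tss_min=0.5)
        np.testing.assert_allclose(w, [0.6, 0.4])

    def test_equal_tss_members_average_scores(self):
        # two members TSS 0.8 each with cell scores 0.2 / 0.6 -> ensemble 0.4
        _, w = fc.build_ensemble([self._member(0.8), self._member(0.8)], tss_min=0.7)
        assert np.dot(w, [0.2, 0.6]) == pytest.approx(0.4)

    def test_no_passing_member_advises_gate(self):
        with pytest.raises(ValueError, match="relax"):
            fc.build_ensemble([self._member(0.3)], tss_min=0.7)

    def test_ensemble_bounded_by_member_scores(self, fitted_ensemble, presence_absence):
        _, X, _ = presence_absence
        s = fitted_ensemble.predict_suitability(X[:50])
        per_member = np.array([member_scores(m.model, X[:50]) for m in fitted_ensemble.members_])
        assert (s >= per_member.min(axis=0) - 1e-12).all()
        assert (s <= per_member.max(axis=0) + 1e-12).all()

    def test_ensemble_at_least_as_good_as_best_member(self, fitted_ensemble):
        best = fitted_ensemble.all_scores_["roc_auc"].max()
        assert fitted_ensemble.pooled_auc_ >= best - 0.02

    def test_parameter_recovery_on_known_truth(self, small_landscape, fitted_ensemble):
        """Ensemble recovers the logistic truth: AUC >= 0.9, rank corr >= 0.8."""
        from scipy.stats import spearmanr

        _, stack, truth = small_landscape
        assert fitted_ensemble.pooled_auc_ >= 0.90
        smap = fitted_ensemble.predict_map(stack)
        rho = spearmanr(smap.S.ravel(), truth.surface(stack).ravel()).statistic
        assert rho >= 0.8


class TestTiers:
    def test_equal_width_band_arithmetic(self):
        """Cutoff 0.25 puts boundaries at 0.50 / 0.75; S=0.6 is moderate."""
        tiers = tier_classify(np.array([[0.6]]), cutoff=0.25)
        assert tiers[0, 0] == 2  # moderate

    def test_cutoff_value_lands_in_low(self):
        tiers = tier_classify(np.array([[0.25]]), cutoff=0.25)
        assert tiers[0, 0] == 1  # low (lower bound inclusive)

    def test_all_below_cutoff_is_all_unsuitable(self):
        geom = GridGeometry(np.r_[100.0, 100.1], np.r_[30.0, 30.1])
        smap = SuitabilityMap(geom, np.full((2, 2), 0.1), cutoff=0.5)
        assert not smap.suitable.any()

    def test_degenerate_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            tier_classify(np.array([0.5]), cutoff=1.0)

    def test_binarize_uses_max_tss_threshold(self, small_landscape, fitted_ensemble):
        _, stack, _ = small_landscape
        S = fitted_ensemble.predict_suitability(stack.to_table().to_numpy()).reshape(
            stack.geometry.shape
        )
        smap = binarize_and_tier(
            S, stack.geometry, fitted_ensemble._pooled_scores, fitted_ensemble._pooled_y
        )
        thr, _ = max_tss_threshold(fitted_ensemble._pooled_y, fitted_ensemble._pooled_scores)
        assert smap.cutoff == pytest.approx(thr)
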