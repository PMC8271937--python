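"""Fusion, matching arithmetic and ROC/AUC/EER evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from plantarkit import biometrics as bm
from plantarkit import phantom
from plantarkit.core import (
    DegenerateFeatureError,
    DimensionError,
    EvaluationError,
    ParameterError,
)


@pytest.fixture(scope="module")
def population():
    return phantom.make_subject_population(
        phantom.PopulationParams(n_subjects=90, n_trials=5, seed=7))


class TestNormalization:
    def test_two_vector_gallery_hits_zero_and_one(self, population):
        two = population.iloc[:2].copy()
        norm_p = bm.normalize_gallery(two)
        normed, _ = bm.apply_normalization(two, norm_p)
        for col in bm.FEATURE_COLUMNS:
            assert set(np.round(normed[col], 12)) == {0.0, 1.0}

    def test_probe_outside_range_clipped_and_counted(self, population):
        norm_p = bm.normalize_gallery(population)
        probe = population.iloc[:1].copy()
        probe[bm.FEATURE_COLUMNS[0]] = 1e6
        normed, clipped = bm.apply_normalization(probe, norm_p)
        assert normed[bm.FEATURE_COLUMNS[0]].iloc[0] == 1.0
        assert clipped == 1

    def test_idempotent_on_normalized_data(self, population):
        norm_p = bm.normalize_gallery(population)
        once, _ = bm.apply_normalization(population, norm_p)
        unit = {c: (0.0, 1.0) for c in bm.FEATURE_COLUMNS}
        twice, clipped = bm.apply_normalization(once, unit)
        assert clipped == 0
        assert np.allclose(once[bm.FEATURE_COLUMNS], twice[bm.FEATURE_COLUMNS])

    def test_constant_feature_rejected(self, population):
        bad = population.copy()
        bad["axis_ratio"] = 2.0
        with pytest.raises(DegenerateFeatureError, match="axis_ratio"):
            bm.normalize_gallery(bad)


class TestAssemble:
    fs = np.array([0.2, 0.5, 0.8])
    fd = np.array([0.1, 0.9, 0.4])

    def test_half_alpha_is_plain_concatenation(self):
        s = bm.assemble_features(self.fs, self.fd, 0.5)
        assert np.array_equal(s, np.concatenate([self.fd, self.fs]))

    def test_alpha_one_zeroes_static(self):
        s = bm.assemble_features(self.fs, self.fd, 1.0)
        assert np.array_equal(s[:3], 2 * self.fd)
        assert np.all(s[3:] == 0.0)

    def test_alpha_zero_zeroes_dynamic(self):
        s = bm.assemble_features(self.fs, self.fd, 0.0)
        assert np.all(s[:3] == 0.0)
        assert np.array_equal(s[3:], 2 * self.fs)

    def test_alpha_out_of_range(self):
        with pytest.raises(ParameterError):
            bm.assemble_features(self.fs, self.fd, 1.2)


class TestMatchingScore:
    def test_identical_vectors_score_one(self):
        v = np.array([0.1, 0.2, 0.3])
        assert bm.matching_error(v, v) == 0.0
        assert bm.matching_score(v, v) == 1.0

    def test_printed_arithmetic(self):
        s = np.array([0.5, 0.5, 0.5])
        t = np.array([0.8, 0.1, 0.5])
        assert bm.matching_error(s, t) == pytest.approx(0.25 / 3)
        assert bm.matching_score(s, t) == pytest.approx(0.91667, abs=5e-6)

    def test_maximal_normalized_error(self):
        s = np.zeros(6)
        t = np.ones(6)
        assert bm.matching_score(s, t) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_symmetry_and_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        s, t = rng.uniform(0, 1, (2, 6))
        assert bm.matching_score(s, t) == bm.matching_score(t, s)
        assert (bm.matching_score(s, t) == 1.0) == bool(np.all(s == t))

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            bm.matching_error(np.zeros(3), np.zeros(4))


class TestScoreAllPairs:
    def test_paper_design_pair_counts(self, population):
        S = population[bm.FEATURE_COLUMNS].to_numpy()
        g, i = bm.score_all_pairs(population["subject_id"].to_numpy(), S)
        assert len(g) == 900          # 90 * C(5, 2)
        assert len(i) == 100_125      # C(450, 2) - 900

    def test_two_by_two(self):
        ids = np.array([0, 0, 1, 1])
        S = np.arange(8, dtype=float).reshape(4, 2)
        g, i = bm.score_all_pairs(ids, S)
        assert len(g) == 2 and len(i) == 4

    def test_single_trial_subjects_only_imposters(self):
        ids = np.array([0, 1, 2, 2])
        S = np.random.default_rng(0).uniform(0, 1, (4, 3))
        g, i = bm.score_all_pairs(ids, S)
        assert len(g) == 1 and len(i) == 5
        with pytest.raises(EvaluationError):
            bm.score_all_pairs(np.array([0, 1]), S[:2])


class TestRocEer:
    def test_perfect_separation(self):
        ev = bm.roc_eer([0.9] * 20, [0.1] * 30)
        assert ev.auc == 1.0
        assert ev.eer == 0.0

    def test_chance_level(self, rng):
        g = rng.normal(0.5, 0.1, 4000)
        i = rng.normal(0.5, 0.1, 4000)
        ev = bm.roc_eer(g, i)
        assert ev.auc == pytest.approx(0.5, abs=0.03)
        assert ev.eer == pytest.approx(0.5, abs=0.03)

    def test_binormal_auc_matches_closed_form(self):
        rng = np.random.default_rng(99)
        g = rng.normal(0.8, 0.05, 10_000)
        i = rng.normal(0.5, 0.10, 10_000)
        ev = bm.roc_eer(g, i)
        expected = norm.cdf(0.3 / np.hypot(0.05, 0.10))
        assert ev.auc == pytest.approx(expected, abs=0.005)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), ng=st.integers(5, 200),
           ni=st.integers(5, 200), ties=st.booleans())
    def test_auc_equals_mann_whitney_oracle(self, seed, ng, ni, ties):
        rng = np.random.default_rng(seed)
        if ties:  # coarse grid forces tied scores across both classes
            g = rng.integers(0, 8, ng) / 8.0
            i = rng.integers(0, 8, ni) / 8.0
        else:
            g = rng.normal(0.7, 0.2, ng)
            i = rng.normal(0.4, 0.2, ni)
        ev = bm.roc_eer(g, i)
        mw = (np.sum(g[:, None] > i[None, :]) + 0.5 * np.sum(g[:, None] == i[None, :]))
        assert ev.auc == pytest.approx(mw / (ng * ni), abs=1e-9)

    def test_roc_monotone_and_empty_rejected(self, rng):
        ev = bm.roc_eer(rng.uniform(0, 1, 50), rng.uniform(0, 1, 50))
        assert np.all(np.diff(ev.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(ev.roc_points[:, 1]) >= 0)
        with pytest.raises(EvaluationError):
            bm.roc_eer([], [0.5])


class TestEvaluatePopulation:
    def test_zero_within_sd_is_perfectly_separable(self):
        pop = phantom.make_subject_population(
            phantom.PopulationParams(n_subjects=10, n_trials=3, seed=0,
                                     within_sd=(0,) * 6))
        ev = bm.evaluate_population(pop)
        assert ev.auc == 1.0
        assert ev.eer == 0.0

    def test_uninformative_identity_is_chance_level(self):
        # subject means carry no information when between-spread is negligible
        aucs = []
        for seed in range(5):
            pop = phantom.make_subject_population(phantom.PopulationParams(
                n_subjects=30, n_trials=4, seed=seed,
                between_sd=tuple(1e-9 * np.ones(6)),
                within_sd=(0.05, 4.0, 0.35, 4.0, 8.0, 0.08)))
            aucs.append(bm.evaluate_population(pop).auc)
        assert 0.45 < np.mean(aucs) < 0.55

    def test_separable_regime_performance(self, population):
        ev = bm.evaluate_population(population, alpha_weight=0.5)
        assert ev.auc >= 0.95
        assert ev.eer <= 0.10

    def test_half_alpha_reproduces_unweighted_pipeline_bitwise(self, population):
        ev = bm.evaluate_population(population, alpha_weight=0.5)
        norm_p = bm.normalize_gallery(population)
        normed, _ = bm.apply_normalization(population, norm_p)
        S = np.hstack([normed[bm.DYNAMIC_COLUMNS].to_numpy(),
                       normed[bm.STATIC_COLUMNS].to_numpy()])
        g, i = bm.score_all_pairs(normed["subject_id"].to_numpy(), S)
        ref = bm.roc_eer(g, i)
        assert ev.auc == ref.auc
        assert ev.eer == ref.eer

    def test_alpha_one_ignores_static_features(self, population):
        corrupted = population.copy()
        rng = np.random.default_rng(0)
        for col in bm.STATIC_COLUMNS:
            corrupted[col] = rng.permutation(corrupted[col].to_numpy())
        ev_a = bm.evaluate_population(population, alpha_weight=1.0)
        ev_b = bm.evaluate_population(corrupted, alpha_weight=1.0)
        assert ev_a.auc == pytest.approx(ev_b.auc, abs=1e-12)

    def test_eer_monotone_in_within_sd(self):
        eers = []
        base = np.array([0.05, 4.0, 0.35, 4.0, 8.0, 0.08])
        for k, f in enumerate([0.1, 0.25, 0.5, 1.0, 2.0]):
            pop = phantom.make_subject_population(phantom.PopulationParams(
                n_subjects=40, n_trials=4, seed=123,
                within_sd=tuple(f * base)))
            eers.append(bm.evaluate_population(pop).eer)
        assert all(a <= b + 1e-12 for a, b in zip(eers, eers[1:]))
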