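"""Logistic fits, ROC/Youden, repeated cross-validation and combo search."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methpanel.classify import (
    auc_mann_whitney,
    cohort_summary,
    combo_search,
    fit_logistic,
    independence_groups,
    marker_stats,
    repeated_cv,
    roc_youden,
    wald_or_ci,
)
from methpanel.simulate import INVALID, SampleAnnotation


def make_calls(rows, samples):
    return pd.DataFrame(rows, index=pd.Index([f"M{i}" for i in range(len(rows))], name="locus"),
                        columns=samples, dtype="int8")


def make_ann(n_pr, n_sd):
    return [SampleAnnotation(f"PR{i:02d}", "PR") for i in range(n_pr)] + [
        SampleAnnotation(f"SD{i:02d}", "SD") for i in range(n_sd)
    ]


def pair_count_auc(scores, labels):
    """Brute-force AUC: P(s+ > s-) + 0.5 P(tie) over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestWaldArithmetic:
    def test_or_equals_exp_beta_and_ci_brackets(self):
        or_, lo, hi = wald_or_ci(1.2, 0.4)
        assert or_ == pytest.approx(math.exp(1.2))
        assert lo < or_ < hi


class TestFitLogistic:
    def test_null_effect_zero_coefficient(self):
        # marker level does not change the outcome rate
        x = np.array([1.0] * 10 + [0.0] * 10)
        y = np.array([1, 1, 1, 0, 0] * 2 + [1, 1, 1, 0, 0] * 2, float)
        fit = fit_logistic(x, y)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-6)

    def test_saturated_fit_equals_sample_log_odds_ratio(self):
        # x=1: 8 events / 2 non-events; x=0: 5 / 5
        x = np.array([1.0] * 10 + [0.0] * 10)
        y = np.array([1] * 8 + [0] * 2 + [1] * 5 + [0] * 5, float)
        fit = fit_logistic(x, y)
        assert fit.beta[1] == pytest.approx(math.log(4.0), abs=1e-6)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-6)  # log(5/5)

    def test_matches_statsmodels_on_random_data(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=(200, 2))
        eta = -0.3 + x @ np.array([0.8, -0.5])
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.beta == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, rel=1e-4)

    def test_separation_flagged_not_raised(self):
        x = np.array([1.0] * 10 + [0.0] * 10)
        y = np.array([1.0] * 10 + [0.0] * 10)
        fit = fit_logistic(x, y, raise_on_failure=False)
        assert fit.separation_warning
        assert fit.predict_proba(np.array([[1.0]]))[0] > 0.99

    def test_ci_invariant_or_exp_beta(self, rng):
        x = rng.normal(size=(80, 1))
        y = (rng.random(80) < 0.5).astype(float)
        fit = fit_logistic(x, y)
        assert np.allclose(fit.or_, np.exp(fit.beta))
        ci = fit.ci95
        assert (ci[:, 0] <= fit.or_).all() and (fit.or_ <= ci[:, 1]).all()


class TestRocYouden:
    def test_tied_pair_example(self):
        roc = roc_youden([0.9, 0.8, 0.7, 0.8], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(3.5 / 4)

    def test_perfect_separation(self):
        roc = roc_youden([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.j == pytest.approx(1.0)
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_degenerate_all_tied(self):
        roc = roc_youden([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(0.5)
        assert roc.j == pytest.approx(0.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_youden([0.4, 0.6], [1, 1])

    def test_accuracy_identity_at_youden_point(self, rng):
        scores = rng.random(60)
        labels = rng.random(60) < 0.4
        roc = roc_youden(scores, labels)
        expected = (roc.sensitivity * roc.n_pos + roc.specificity * roc.n_neg) / (
            roc.n_pos + roc.n_neg
        )
        assert roc.accuracy == pytest.approx(expected)

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = np.round(rng.random(100), 2)  # rounding forces ties
        labels = rng.random(100) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    @given(
        st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=1, max_size=8),
        st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=1, max_size=8),
    )
    def test_auc_equals_pair_counting_oracle(self, pos, neg):
        scores = pos + neg
        labels = [1] * len(pos) + [0] * len(neg)
        assert auc_mann_whitney(np.array(scores), np.array(labels, bool)) == pytest.approx(
            pair_count_auc(scores, labels)
        )


class TestRepeatedCv:
    def test_perfect_marker(self):
        ann = make_ann(10, 10)
        calls = make_calls([[1] * 10 + [0] * 10], [a.sample_id for a in ann])
        rep = repeated_cv(calls, ann, ("M0",), repeats=10, folds=5, seed=4)
        assert rep.mean_auc == pytest.approx(1.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_same_seed_identical_report(self, rng):
        ann = make_ann(12, 10)
        calls = make_calls([(rng.random(22) < 0.5).astype(int)], [a.sample_id for a in ann])
        a = repeated_cv(calls, ann, ("M0",), repeats=8, folds=5, seed=7)
        b = repeated_cv(calls, ann, ("M0",), repeats=8, folds=5, seed=7)
        assert np.array_equal(a.auc_per_repeat, b.auc_per_repeat)
        assert a.to_dict() == b.to_dict()

    def test_null_marker_auc_near_half(self, rng):
        n = 60
        ann = make_ann(n, n)
        calls = make_calls([(rng.random(2 * n) < 0.5).astype(int)], [a.sample_id for a in ann])
        rep = repeated_cv(calls, ann, ("M0",), repeats=30, folds=5, seed=11)
        se0 = np.sqrt((2 * n + 1) / (12 * n * n))
        assert abs(rep.mean_auc - 0.5) <= 3 * se0

    def test_invalid_calls_drop_samples(self):
        ann = make_ann(10, 10)
        row = [1] * 10 + [0] * 10
        row[0] = INVALID
        calls = make_calls([row], [a.sample_id for a in ann])
        rep = repeated_cv(calls, ann, ("M0",), repeats=3, folds=5, seed=2)
        assert rep.n_dropped == 1
        assert rep.n_used == 19

    def test_too_few_per_class_rejected(self):
        ann = make_ann(10, 3)
        calls = make_calls([[1] * 13], [a.sample_id for a in ann])
        with pytest.raises(ValueError, match="stratified"):
            repeated_cv(calls, ann, ("M0",), repeats=2, folds=5)


class TestMarkerStats:
    def test_perfect_marker_delta_and_auc(self):
        ann = make_ann(10, 10)
        calls = make_calls([[1] * 10 + [0] * 10], [a.sample_id for a in ann])
        stats = marker_stats(calls, ann, cv_params={"repeats": 5, "folds": 5, "seed": 1})
        assert stats.loc["M0", "delta"] == pytest.approx(1.0)
        assert stats.loc["M0", "cv_auc"] == pytest.approx(1.0)

    def test_identical_frequencies_zero_delta(self):
        ann = make_ann(6, 6)
        calls = make_calls([[1, 1, 1, 0, 0, 0] * 2], [a.sample_id for a in ann])
        stats = marker_stats(calls, ann)
        assert stats.loc["M0", "delta"] == pytest.approx(0.0)

    def test_group_without_valid_cells_flagged(self):
        ann = make_ann(5, 5)
        calls = make_calls([[1] * 5 + [INVALID] * 5], [a.sample_id for a in ann])
        stats = marker_stats(calls, ann)
        assert stats.loc["M0", "flagged"]
        assert np.isnan(stats.loc["M0", "freq_sd"])

    def test_delta_correlates_with_single_marker_auc(self, rng):
        """Frequency deltas above 5% should track cross-validated AUC."""
        ann = make_ann(30, 30)
        deltas = [0.1, 0.25, 0.4, 0.55, 0.7, 0.85]
        rows = []
        for d in deltas:
            f_pr, f_sd = 0.5 + d / 2, 0.5 - d / 2
            rows.append(np.concatenate([
                rng.random(30) < f_pr, rng.random(30) < f_sd
            ]).astype(int))
        calls = make_calls(rows, [a.sample_id for a in ann])
        stats = marker_stats(calls, ann, cv_params={"repeats": 10, "folds": 5, "seed": 3})
        from scipy.stats import spearmanr

        rho, _ = spearmanr(stats["delta"].abs(), stats["cv_auc"])
        assert rho > 0


class TestIndependenceGroups:
    def test_identical_pair_grouped_together(self, rng):
        base = (rng.random(20) < 0.5).astype(int)
        rows = [base, base.copy(), 1 - base, 1 - base.copy()]
        calls = make_calls(rows, [f"s{i}" for i in range(20)])
        labels, pca, _ = independence_groups(calls, k=2)
        assert labels["M0"] == labels["M1"]
        assert labels["M2"] == labels["M3"]
        assert labels["M0"] != labels["M2"]
        assert pca.shape == (4, 2)

    def test_planted_two_block_recovery(self, rng):
        block = (rng.random(24) < 0.5).astype(int)
        other = (rng.random(24) < 0.5).astype(int)
        rows = [block ^ (rng.random(24) < 0.05) for _ in range(3)]
        rows += [other ^ (rng.random(24) < 0.05) for _ in range(3)]
        calls = make_calls([r.astype(int) for r in rows], [f"s{i}" for i in range(24)])
        labels, _, _ = independence_groups(calls, k=2)
        assert len(set(labels.iloc[:3])) == 1
        assert len(set(labels.iloc[3:])) == 1

    def test_sample_permutation_invariant(self, rng):
        rows = [(rng.random(16) < 0.5).astype(int) for _ in range(4)]
        calls = make_calls(rows, [f"s{i}" for i in range(16)])
        perm = calls[list(np.random.default_rng(1).permutation(calls.columns))]
        a, _, _ = independence_groups(calls, k=2)
        b, _, _ = independence_groups(perm, k=2)
        assert (a == b).all() or (a.map({1: 2, 2: 1}) == b).all()


class TestComboSearch:
    def test_exhaustive_subset_count(self, rng):
        ann = make_ann(10, 10)
        rows = [(rng.random(20) < 0.5).astype(int) for _ in range(4)]
        calls = make_calls(rows, [a.sample_id for a in ann])
        reports = combo_search(calls, ann, list(calls.index), max_size=3,
                               repeats=2, folds=5, seed=5)
        assert len(reports) == 4 + 6 + 4  # C(4,1)+C(4,2)+C(4,3)

    def test_perfect_marker_singleton_wins_by_simplicity(self, rng):
        ann = make_ann(10, 10)
        perfect = [1] * 10 + [0] * 10
        noise = (rng.random(20) < 0.5).astype(int)
        calls = make_calls([perfect, noise], [a.sample_id for a in ann])
        reports = combo_search(calls, ann, ["M0", "M1"], max_size=2,
                               repeats=5, folds=5, seed=6)
        assert reports[0].combo == ("M0",)
        assert reports[0].mean_auc == pytest.approx(1.0)

    def test_complementary_pair_beats_singletons(self):
        # y=1 iff either marker fires; each alone is weak, the pair separates
        ann = make_ann(10, 10)
        m_a = [1] * 5 + [0] * 5 + [0] * 10
        m_b = [0] * 5 + [1] * 5 + [0] * 10
        calls = make_calls([m_a, m_b], [a.sample_id for a in ann])
        reports = combo_search(calls, ann, ["M0", "M1"], max_size=2,
                               repeats=10, folds=5, seed=8)
        assert reports[0].combo == ("M0", "M1")
        singles = [r.mean_auc for r in reports if len(r.combo) == 1]
        assert reports[0].mean_auc > max(singles)

    def test_cross_group_constraint_excludes_within_group_pairs(self, rng):
        ann = make_ann(10, 10)
        rows = [(rng.random(20) < 0.5).astype(int) for _ in range(3)]
        calls = make_calls(rows, [a.sample_id for a in ann])
        groups = pd.Series({"M0": 1, "M1": 1, "M2": 2})
        reports = combo_search(calls, ann, ["M0", "M1", "M2"], max_size=2,
                               repeats=2, folds=5, seed=9, groups=groups,
                               cross_group_only=True)
        combos = {r.combo for r in reports}
        assert ("M0", "M1") not in combos
        assert ("M0", "M2") in combos


class TestCohortSummary:
    def test_percentages(self):
        summary = cohort_summary(make_ann(27, 10))
        assert summary.loc[0, "percent"] == 72.97
        assert summary.loc[1, "percent"] == 27.03
        summary1 = cohort_summary(make_ann(15, 10))
        assert summary1.loc[0, "percent"] == 60.0
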