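"""Splits, ROC/AUC, cutoff selection, exact intervals, DeLong."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmrtriage import (
    EvaluationError,
    auc_from_roc,
    binomial_ci,
    confusion_eval,
    delong_auc_variance,
    delong_compare,
    per_protein_sensitivity,
    random_split,
    roc_auc,
    roc_curve,
    select_cutoff,
)


def concordance_auc(scores, labels):
    """Brute-force pairwise concordance: P(pathological scores below
    normal), ties counting one half."""
    s = np.asarray(scores, float)
    lab = np.asarray(labels, bool)
    p, q = s[lab], s[~lab]
    total = sum(float((x < q).sum()) + 0.5 * float((x == q).sum()) for x in p)
    return total / (len(p) * len(q))


def exhaustive_youden(scores, labels):
    """Best J over every midpoint threshold, by direct enumeration."""
    s = np.asarray(scores, float)
    lab = np.asarray(labels, bool)
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    return max((s[lab] < c).mean() - (s[~lab] < c).mean() for c in cands)


class TestRandomSplit:
    def test_study_split_sizes(self):
        ids = np.array([f"C{i}" for i in range(323)])
        test, val = random_split(ids, 146 / 323, seed=0)
        assert (len(test), len(val)) == (146, 177)

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        ids = np.arange(57)
        test, val = random_split(ids, 0.4, seed=3)
        assert set(test) | set(val) == set(ids)
        assert set(test) & set(val) == set()

    def test_deterministic_per_seed(self):
        ids = np.arange(100)
        assert np.array_equal(
            random_split(ids, 0.3, seed=8)[0], random_split(ids, 0.3, seed=8)[0]
        )

    def test_empty_input_rejected(self):
        with pytest.raises(EvaluationError):
            random_split(np.array([]), 0.5, seed=0)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        scores = np.array([1, 2, 3, 10, 11, 12], float)
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        assert roc_auc(scores, labels) == pytest.approx(1.0)

    def test_all_ties_auc_half(self):
        scores = np.ones(8)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1], bool)
        assert roc_auc(scores, labels) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_curve(np.arange(5.0), np.ones(5, bool))

    def test_roc_coordinates_monotone(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        roc = roc_curve(scores, labels)
        assert (np.diff(roc["fpr"]) >= 0).all()
        assert (np.diff(roc["tpr"]) >= 0).all()

    def test_auc_equals_concordance_on_random_instances(self, rng):
        """Trapezoid AUC == Mann-Whitney concordance on 50 random
        20-core instances with heavy ties."""
        for _ in range(50):
            labels = np.zeros(20, bool)
            labels[: rng.integers(1, 20)] = True
            scores = rng.choice(np.arange(8.0), size=20)
            assert roc_auc(scores, labels) == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12
            )

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.35
        # sklearn scores are higher-is-positive; negate ours
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, -scores), abs=1e-12
        )

    @given(shift=st.floats(min_value=0.1, max_value=10), scale=st.floats(min_value=0.1, max_value=5))
    @settings(max_examples=25, derandomize=True)
    def test_rank_invariance(self, shift, scale):
        """Strictly increasing transforms leave ROC and AUC unchanged."""
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        transformed = np.exp(scale * scores) + shift
        a = roc_curve(scores, labels)
        b = roc_curve(transformed, labels)
        np.testing.assert_allclose(a[["fpr", "tpr"]], b[["fpr", "tpr"]])
        assert auc_from_roc(a) == pytest.approx(auc_from_roc(b), abs=1e-12)


class TestSelectCutoff:
    def test_perfect_separation_returns_gap_midpoint(self):
        scores = np.array([1, 2, 3, 10, 11, 12], float)
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        cutoff, j = select_cutoff(roc_curve(scores, labels))
        assert cutoff == pytest.approx(6.5)
        assert j == pytest.approx(1.0)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            labels = np.zeros(10, bool)
            labels[: rng.integers(1, 10)] = True
            scores = rng.normal(size=10).round(1)
            _, j = select_cutoff(roc_curve(scores, labels))
            assert j == pytest.approx(exhaustive_youden(scores, labels), abs=1e-12)

    def test_selected_cutoff_dominates_all_thresholds(self, rng):
        """J at the selected cutoff is never beaten by any other
        threshold on the same data."""
        scores = rng.normal(size=35)
        labels = rng.random(35) < 0.4
        roc = roc_curve(scores, labels)
        cutoff, j = select_cutoff(roc)
        lab = np.asarray(labels, bool)
        for c in np.linspace(scores.min() - 1, scores.max() + 1, 400):
            assert (scores[lab] < c).mean() - (scores[~lab] < c).mean() <= j + 1e-12


class TestBinomialCi:
    @pytest.mark.parametrize(
        "x,n,lo,hi",
        [
            (37, 44, 69.9, 93.4),
            (54, 102, 42.8, 62.9),
            (53, 54, 90.1, 100.0),
            (68, 123, 46.1, 64.3),
            (112, 112, 96.8, 100.0),
        ],
    )
    def test_two_sided_exact_bounds(self, x, n, lo, hi):
        got = binomial_ci(x, n, 0.95, "two")
        assert got[0] == pytest.approx(lo, abs=0.05)
        assert got[1] == pytest.approx(hi, abs=0.05)

    def test_one_sided_lower_limits(self):
        assert binomial_ci(112, 112, sided="lower_one")[0] == pytest.approx(97.4, abs=0.05)
        assert binomial_ci(278, 278, sided="lower_one")[0] == pytest.approx(98.9, abs=0.05)

    def test_boundary_cases(self):
        assert binomial_ci(0, 10)[0] == 0.0
        assert binomial_ci(10, 10)[1] == 100.0

    @pytest.mark.parametrize("x,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts_rejected(self, x, n):
        with pytest.raises(EvaluationError):
            binomial_ci(x, n)

    def test_coverage_is_conservative(self):
        """Exact intervals cover the true p at or above the nominal
        level: 2,000 simulated binomials at each p in {0.1, 0.5, 0.9},
        n = 50."""
        rng = np.random.default_rng(99)
        n = 50
        for p in (0.1, 0.5, 0.9):
            xs = rng.binomial(n, p, size=2000)
            covered = 0
            for x in np.unique(xs):
                lo, hi = binomial_ci(int(x), n)
                if lo <= 100 * p <= hi:
                    covered += (xs == x).sum()
            assert covered / 2000 >= 0.95


class TestConfusionEval:
    def test_perfect_and_inverted_predictions(self):
        truth = pd.Series(["pathological"] * 5 + ["normal"] * 5)
        perfect = confusion_eval(truth, truth)
        assert (perfect.sensitivity, perfect.specificity) == (100.0, 100.0)
        inverted = confusion_eval(
            truth.map({"pathological": "normal", "normal": "pathological"}), truth
        )
        assert (inverted.sensitivity, inverted.specificity) == (0.0, 0.0)

    def test_validation_set_counts(self):
        """TP=53 FN=1 TN=72 FP=51 gives sensitivity 53/54 ~ 98.1% with
        CI [90.1, 100] and specificity 72/123 ~ 58.5% [49.3, 67.3]."""
        pred = ["pathological"] * 53 + ["normal"] + ["normal"] * 72 + ["pathological"] * 51
        truth = ["pathological"] * 54 + ["normal"] * 123
        rep = confusion_eval(pred, truth)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (53, 1, 72, 51)
        assert rep.sensitivity == pytest.approx(98.15, abs=0.05)
        assert rep.specificity == pytest.approx(58.5, abs=0.05)
        assert rep.sensitivity_ci[0] == pytest.approx(90.1, abs=0.05)
        assert rep.sensitivity_ci[1] == pytest.approx(100.0, abs=0.05)
        assert rep.specificity_ci == pytest.approx((49.3, 67.3), abs=0.05)

    def test_mismatched_ids_rejected(self):
        a = pd.Series(["normal"] * 3, index=["c1", "c2", "c3"])
        b = pd.Series(["normal"] * 3, index=["c1", "c2", "c9"])
        with pytest.raises(EvaluationError):
            confusion_eval(a, b)

    def test_per_protein_sensitivity(self):
        sections = pd.DataFrame(
            {
                "protein": ["MLH1"] * 4 + ["PMS2"] * 2,
                "stained": [False, False, True, True, False, False],
                "sis": [1.0, 60.0, 70.0, 80.0, 2.0, 3.0],
            }
        )
        out = per_protein_sensitivity(sections, cutoff=55.0)
        assert out["MLH1"] == pytest.approx(50.0)
        assert out["PMS2"] == pytest.approx(100.0)
        assert "MSH2" not in out


class TestDelong:
    def _instance(self, seed=0, n=30, n_path=12):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, bool)
        labels[:n_path] = True
        scores = np.where(labels, rng.normal(0, 1, n), rng.normal(1.2, 1, n))
        return scores, labels

    def test_identical_scores_give_null_result(self):
        scores, labels = self._instance()
        auc_a, auc_b, z, p = delong_compare(scores, scores, labels)
        assert auc_a == auc_b
        assert z == 0.0
        assert p == 1.0

    def test_monotone_transform_has_zero_auc_difference(self):
        scores, labels = self._instance(seed=4)
        auc_a, auc_b, z, p = delong_compare(scores, np.exp(scores), labels)
        assert auc_a == pytest.approx(auc_b, abs=1e-12)
        assert p == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            delong_compare(np.arange(4.0), np.arange(4.0), np.ones(4, bool))

    def test_variance_close_to_bootstrap(self):
        """DeLong AUC variance within 20% of a 10,000-rep stratified
        bootstrap on a 30-core instance."""
        scores, labels = self._instance(seed=1)
        auc, var = delong_auc_variance(scores, labels)
        rng = np.random.default_rng(7)
        p, q = scores[labels], scores[~labels]
        reps = np.empty(10_000)
        for i in range(reps.size):
            pb = rng.choice(p, p.size)
            qb = rng.choice(q, q.size)
            reps[i] = concordance_auc(
                np.concatenate([pb, qb]),
                np.concatenate([np.ones(p.size, bool), np.zeros(q.size, bool)]),
            )
        boot_var = reps.var(ddof=1)
        assert abs(var - boot_var) <= 0.2 * boot_var
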