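import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mircascade import (
    ConfusionCounts,
    classification_metrics,
    confusion_counts,
    dagostino_pearson,
    roc_auc,
    spearman_rho,
    youden_cutoff,
)
from mircascade.stats import auc_only


def brute_force_auc(scores, status):
    """Independent oracle: average pairwise case-over-control indicator."""
    cases = [s for s, y in zip(scores, status) if y == 1]
    ctrls = [s for s, y in zip(scores, status) if y == 0]
    total = 0.0
    for c in cases:
        for k in ctrls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(ctrls))


def brute_force_youden(scores, status, polarity):
    oriented = np.asarray(scores, float) * polarity
    distinct = np.unique(oriented)
    cuts = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))
    status = np.asarray(status)
    best = (-np.inf, np.inf, 0.0, 0.0)
    for c in cuts:
        pred = oriented >= c
        sens = np.sum(pred & (status == 1)) / np.sum(status == 1)
        spec = np.sum(~pred & (status == 0)) / np.sum(status == 0)
        j = sens + spec - 1
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and c < best[1]):
            best = (j, float(c), float(sens), float(spec))
    return best[1], best[2], best[3]


class TestRocAuc:
    def test_worked_example(self):
        # cases [0.9, 0.8, 0.4] vs controls [0.3, 0.5, 0.2]: 8 of 9 pairs won
        scores = [0.9, 0.8, 0.4, 0.3, 0.5, 0.2]
        status = [1, 1, 1, 0, 0, 0]
        r = roc_auc(scores, status)
        assert r.auc == pytest.approx(8 / 9)
        assert r.polarity == 1

    def test_tie_counts_half(self):
        r = roc_auc([0.5, 0.5], [1, 0])
        assert r.auc == 0.5

    def test_perfect_separation(self):
        r = roc_auc([1.0, 0.9, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0
        assert r.specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty|length"):
            roc_auc([], [])

    def test_brute_force_equivalence_exact(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1 = int(rng.integers(2, 25))
            n0 = int(rng.integers(2, 25))
            status = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            scores = np.round(rng.normal(size=n1 + n0), 1)  # ties likely
            assert auc_only(scores, status) == brute_force_auc(scores, status)

    def test_polarity_flip(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3, 0.5, 0.2])
        status = np.array([1, 1, 1, 0, 0, 0])
        r_pos = roc_auc(scores, status)
        r_neg = roc_auc(-scores, status)
        assert r_neg.auc == r_pos.auc
        assert r_neg.polarity == -r_pos.polarity

    @settings(max_examples=30, deadline=None)
    @given(
        n1=st.integers(2, 15),
        n0=st.integers(2, 15),
        seed=st.integers(0, 2**31),
    )
    def test_monotone_transform_invariance(self, n1, n0, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n1 + n0)
        status = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        a = roc_auc(scores, status).auc
        b = roc_auc(np.exp(scores) + 3, status).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_hanley_mcneil_se_formula(self):
        scores = [0.9, 0.8, 0.4, 0.3, 0.5, 0.2]
        status = [1, 1, 1, 0, 0, 0]
        r = roc_auc(scores, status)
        a = 8 / 9
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + 2 * (q1 - a * a) + 2 * (q2 - a * a)) / 9
        assert r.se == pytest.approx(np.sqrt(var))

    def test_p_value_matches_mannwhitney_asymptotic(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n1, n0 = rng.integers(5, 30, 2)
            scores = np.round(rng.normal(size=int(n1 + n0)), 1)
            status = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            ref = sps.mannwhitneyu(
                scores[status == 1],
                scores[status == 0],
                alternative="two-sided",
                method="asymptotic",
                use_continuity=False,
            ).pvalue
            assert roc_auc(scores, status).p_value == pytest.approx(ref, abs=1e-12)

    def test_sens_spec_consistent_with_cutoff(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=60)
        status = (rng.random(60) < 0.4).astype(int)
        status[:2] = [0, 1]
        r = roc_auc(scores, status)
        pred = (scores * r.polarity >= r.cutoff).astype(int)
        c = confusion_counts(pred, status)
        sens, spec, _ = classification_metrics(c)
        assert sens / 100 == pytest.approx(r.sensitivity)
        assert spec / 100 == pytest.approx(r.specificity)


class TestYoudenCutoff:
    def test_worked_example(self):
        scores = [0.9, 0.8, 0.4, 0.3, 0.5, 0.2]
        status = [1, 1, 1, 0, 0, 0]
        cutoff, sens, spec = youden_cutoff(scores, status, 1)
        assert 0.3 < cutoff < 0.4
        assert sens == 1.0
        assert spec == pytest.approx(2 / 3)

    def test_perfect_separation(self):
        _, sens, spec = youden_cutoff([3.0, 2.0, 1.0, 0.0], [1, 1, 0, 0], 1)
        assert sens == 1.0 and spec == 1.0

    def test_identical_distributions_zero_j(self):
        scores = [1.0, 2.0, 1.0, 2.0]
        status = [1, 1, 0, 0]
        _, sens, spec = youden_cutoff(scores, status, 1)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n1, n0 = rng.integers(2, 20, 2)
            scores = np.round(rng.normal(size=int(n1 + n0)), 1)
            status = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            pol = 1 if rng.random() < 0.5 else -1
            assert youden_cutoff(scores, status, pol) == brute_force_youden(
                scores, status, pol
            )

    def test_bad_polarity_rejected(self):
        with pytest.raises(ValueError, match="polarity"):
            youden_cutoff([1.0, 2.0], [1, 0], 0)


class TestClassificationMetrics:
    def test_worked_example(self):
        sens, spec, acc = classification_metrics(ConfusionCounts(95, 3, 97, 5))
        assert (sens, spec, acc) == (95.0, 97.0, 96.0)

    def test_perfect(self):
        assert classification_metrics(ConfusionCounts(10, 0, 20, 0)) == (
            100.0,
            100.0,
            100.0,
        )

    def test_zero_sensitivity(self):
        sens, _, _ = classification_metrics(ConfusionCounts(0, 0, 20, 10))
        assert sens == 0.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            classification_metrics(ConfusionCounts(0, 5, 5, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)

    @settings(max_examples=40, deadline=None)
    @given(
        tp=st.integers(0, 50),
        fn=st.integers(0, 50),
        tn=st.integers(0, 50),
        fp=st.integers(0, 50),
    )
    def test_weighted_identity(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        sens, spec, acc = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
        p, n = tp + fn, tn + fp
        assert acc == pytest.approx((sens * p + spec * n) / (p + n))


class TestSpearman:
    def test_worked_example(self):
        # d = (-2, 1, 1): rho = 1 - 6*6/(3*8) = -0.5
        assert spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_strictly_monotone(self):
        x = np.array([0.1, 1.4, 2.0, 5.5])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_reverse_sorted(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spearman_rho([1.0, 2.0], [2.0, 1.0])

    def test_d_squared_closed_form_no_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            d = sps.rankdata(x) - sps.rankdata(y)
            expected = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
            assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_midrank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = np.round(rng.normal(size=n), 0)
            y = np.round(rng.normal(size=n), 0)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)


class TestDagostinoPearson:
    def test_symmetric_sample_small_skew_term(self):
        # exactly symmetric sample: the skewness z-score contributes ~0
        x = np.concatenate([np.linspace(-3, 3, 50)])
        z1 = sps.skewtest(x).statistic
        r = dagostino_pearson(x)
        assert abs(z1) < 1e-8
        assert r.k2_statistic == pytest.approx(sps.kurtosistest(x).statistic ** 2)

    def test_lognormal_strongly_rejected(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.standard_normal(500))
        assert dagostino_pearson(x).p_value < 1e-4

    def test_p_decreases_as_k2_increases(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(200)
        skewed = np.exp(rng.standard_normal(200))
        a, b = dagostino_pearson(base), dagostino_pearson(skewed)
        assert b.k2_statistic > a.k2_statistic
        assert b.p_value < a.p_value

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="8"):
            dagostino_pearson(np.arange(7.0))

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dagostino_pearson(np.full(20, 3.0))
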