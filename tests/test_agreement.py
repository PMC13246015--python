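"""Agreement statistics against independent oracles."""

import itertools

import numpy as np
import pytest

from regresponse import (
    SurvivalRecord,
    bootstrap_ci,
    ccc_bands,
    ccc_z_test,
    fleiss_kappa,
    gci,
    harrell_c,
    lin_ccc,
    occc,
    wilcoxon_signed_rank,
)
from conftest import random_blob_mask


# ---------------------------------------------------------------------------
# oracles (independent implementations used only by tests)
# ---------------------------------------------------------------------------


def gci_oracle(arrays):
    inter = union = 0
    for a, b in itertools.combinations(arrays, 2):
        inter += int(np.sum(a & b))
        union += int(np.sum(a | b))
    return inter / union


def fleiss_oracle(labels):
    """Direct evaluation of the defining formulas on a label matrix."""
    n, j = labels.shape
    cats = sorted({str(c) for c in labels.ravel()})
    counts = np.array([[np.sum(labels[i] == c) for c in cats] for i in range(n)], dtype=float)
    p_i = (np.sum(counts**2, axis=1) - j) / (j * (j - 1))
    p_bar = p_i.mean()
    p_c = counts.sum(axis=0) / (n * j)
    p_e = np.sum(p_c**2)
    return (p_bar - p_e) / (1 - p_e)


def harrell_oracle(scores, times, events):
    """Explicit all-pairs enumeration of the concordance definition."""
    num, usable = 0.0, 0
    n = len(scores)
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                if events[i] + events[j] != 1:
                    continue
                short, long_ = (i, j) if events[i] == 1 else (j, i)
            elif times[i] < times[j]:
                if events[i] != 1:
                    continue
                short, long_ = i, j
            else:
                if events[j] != 1:
                    continue
                short, long_ = j, i
            usable += 1
            if scores[short] > scores[long_]:
                num += 1
            elif scores[short] == scores[long_]:
                num += 0.5
    return num / usable


def wilcoxon_enumeration_oracle(diffs):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    mean = total / 2
    ws = np.array([sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)])
    lo = np.mean(ws <= w_obs)
    hi = np.mean(ws >= w_obs)
    if w_obs == mean:
        return 1.0
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------
# GCI
# ---------------------------------------------------------------------------


class TestGci:
    def test_identical_masks_give_one(self):
        rng = np.random.default_rng(0)
        m = random_blob_mask(rng)
        assert gci([m, m, m, m]) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((8, 8, 4), bool)
        b = a.copy()
        c = a.copy()
        a[0, 0, 0] = b[1, 1, 1] = c[2, 2, 2] = True
        assert gci([a, b, c]) == 0.0

    def test_two_mask_counts_and_dice_relation(self):
        # |intersection| = 4, |union| = 12 -> GCI 1/3; Dice = 2G/(1+G) = 0.5
        a = np.zeros((8, 8, 4), bool)
        b = np.zeros((8, 8, 4), bool)
        a.flat[:8] = True
        b.flat[4:12] = True
        g = gci([a, b])
        assert g == pytest.approx(1 / 3)
        dice = 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))
        assert dice == pytest.approx(2 * g / (1 + g))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_and_jaccard(self, seed):
        rng = np.random.default_rng(seed)
        masks = [random_blob_mask(rng) for _ in range(rng.integers(2, 5))]
        assert gci(masks) == pytest.approx(gci_oracle(masks), abs=1e-12)
        if len(masks) == 2:
            jac = np.sum(masks[0] & masks[1]) / np.sum(masks[0] | masks[1])
            assert gci(masks) == pytest.approx(jac)

    def test_all_empty_undefined(self):
        z = np.zeros((8, 8, 4), bool)
        with pytest.raises(ValueError, match="empty"):
            gci([z, z])


# ---------------------------------------------------------------------------
# CCC / OCCC
# ---------------------------------------------------------------------------


class TestCcc:
    def test_identity_and_reflection(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert lin_ccc(x, x) == pytest.approx(1.0)
        y = np.array([1.0, -2.0, 2.0, -1.0])
        assert lin_ccc(y, -y) == pytest.approx(-1.0)

    def test_hand_evaluated_fixture(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 0.1
        # cov = var = 1.25 (population), mean shift 0.1:
        # CCC = 2*1.25 / (1.25 + 1.25 + 0.01) = 2.5/2.51
        assert lin_ccc(x, y) == pytest.approx(2.5 / 2.51, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_occc_reduces_to_lin_ccc_for_two_readers(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(12, 2))
        assert occc(data) == pytest.approx(lin_ccc(data[:, 0], data[:, 1]), abs=1e-12)

    def test_occc_identical_columns(self):
        col = np.array([1.0, 4.0, 2.0, 8.0])
        assert occc(np.column_stack([col] * 3)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_occc_bounded_by_pairwise_extremes(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1))
        pairwise = [lin_ccc(data[:, a], data[:, b]) for a, b in itertools.combinations(range(4), 2)]
        v = occc(data)
        assert min(pairwise) - 1e-12 <= v <= max(pairwise) + 1e-12

    def test_occc_permutation_invariant(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(15, 4))
        v = occc(data)
        assert occc(data[:, ::-1]) == pytest.approx(v, abs=1e-12)
        assert occc(data[::-1, :]) == pytest.approx(v, abs=1e-12)

    def test_constant_matrix_undefined(self):
        with pytest.raises(ValueError):
            occc(np.ones((5, 3)))

    @pytest.mark.parametrize(
        "value,band",
        [(0.29, "poor"), (0.3, "fair"), (0.59, "fair"), (0.6, "moderate"), (0.79, "moderate"), (0.8, "strong"), (0.95, "strong")],
    )
    def test_bands(self, value, band):
        assert ccc_bands(value) == band


class TestCccZTest:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(20, 3)) + rng.normal(size=(20, 1))
        z, p = ccc_z_test(data, data, reps=200, seed=0)
        assert abs(z) < 1e-9 and p == pytest.approx(1.0)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(40, 1))
        a = t + 0.2 * rng.normal(size=(40, 3))
        b = t + 1.5 * rng.normal(size=(40, 3))
        z1, p1 = ccc_z_test(a, b, reps=300, seed=5)
        z2, p2 = ccc_z_test(b, a, reps=300, seed=5)
        assert z1 == pytest.approx(-z2, rel=0.2)
        assert z1 > 0

    def test_detects_large_difference(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=(50, 1))
        strong = t + 0.23 * rng.normal(size=(50, 4))  # true CCC ~ 0.9
        weak = t + 2.0 * rng.normal(size=(50, 4))  # true CCC ~ 0.2
        _, p = ccc_z_test(strong, weak, reps=1000, seed=7)
        assert p < 0.05

    def test_input_validation(self):
        data = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="reps"):
            ccc_z_test(data, data, reps=50)
        with pytest.raises(ValueError, match="5 subjects"):
            ccc_z_test(data[:3], data[:3])


# ---------------------------------------------------------------------------
# Fleiss kappa
# ---------------------------------------------------------------------------


class TestFleissKappa:
    def test_perfect_agreement(self):
        labels = np.array([["PR"] * 4, ["SD"] * 4, ["PD"] * 4, ["PR"] * 4])
        res = fleiss_kappa(labels, reps=200)
        assert res.value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(["CR", "PR", "SD", "PD"], size=(6, 3))
        if len(set(labels.ravel())) < 2:
            pytest.skip("degenerate draw")
        res = fleiss_kappa(labels, reps=100, seed=seed)
        assert res.value == pytest.approx(fleiss_oracle(labels), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa as sm_kappa

        rng = np.random.default_rng(11)
        labels = rng.choice(["A", "B", "C"], size=(25, 4))
        table, _ = aggregate_raters(labels)
        assert fleiss_kappa(labels, reps=100).value == pytest.approx(sm_kappa(table), abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["CR", "PR", "SD"], size=(10, 4))
        swapped = np.where(labels == "CR", "XX", labels)
        assert fleiss_kappa(labels, reps=100).value == pytest.approx(
            fleiss_kappa(swapped, reps=100).value, abs=1e-12
        )

    def test_degenerate_single_category_flagged(self):
        labels = np.full((6, 4), "SD")
        res = fleiss_kappa(labels, reps=100)
        assert res.value == 1.0
        assert res.metadata["degenerate"] is True


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------


class TestHarrellC:
    def test_perfect_ordering(self):
        times = np.array([10.0, 20, 30, 40, 50])
        events = np.ones(5, int)
        scores = -times  # higher score = shorter survival
        assert harrell_c(scores, (times, events)) == 1.0

    def test_all_tied_scores(self):
        times = np.array([10.0, 20, 30, 40])
        assert harrell_c(np.zeros(4), (times, np.ones(4, int))) == 0.5

    def test_mixed_censoring_fixture_matches_oracle(self):
        times = np.array([5.0, 5.0, 8.0, 12.0, 12.0, 20.0, 25.0, 30.0])
        events = np.array([1, 0, 1, 1, 1, 0, 1, 0])
        scores = np.array([3.1, 2.0, 2.0, 1.5, 2.5, 0.5, 1.0, 0.2])
        assert harrell_c(scores, (times, events)) == pytest.approx(
            harrell_oracle(scores, times, events), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        times = np.round(rng.exponential(100, n), -1) + 10  # induce ties
        events = rng.integers(0, 2, n)
        scores = np.round(rng.normal(size=n), 1)
        if events.sum() == 0:
            pytest.skip("no events drawn")
        assert harrell_c(scores, (times, events)) == pytest.approx(
            harrell_oracle(scores, times, events), abs=1e-12
        )

    def test_matches_lifelines_without_ties(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(5)
        times = rng.exponential(100, 30)
        events = rng.integers(0, 2, 30)
        scores = rng.normal(size=30)
        # lifelines treats higher prediction as longer survival
        assert harrell_c(scores, (times, events)) == pytest.approx(
            concordance_index(times, -scores, events), abs=1e-12
        )

    def test_reversal_identity(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(100, 20)
        events = rng.integers(0, 2, 20)
        scores = rng.normal(size=20)
        c = harrell_c(scores, (times, events))
        assert harrell_c(-scores, (times, events)) == pytest.approx(1 - c, abs=1e-12)

    def test_accepts_survival_records(self):
        recs = [SurvivalRecord(f"P{i}", float(10 + i), 1, "OS") for i in range(5)]
        assert harrell_c(np.array([5, 4, 3, 2, 1.0]), recs) == 1.0


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_matches_sign_enumeration_at_n10(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = np.round(rng.normal(size=10), 1)
            d = d[d != 0]
            if len(d) < 3:
                continue
            assert wilcoxon_signed_rank(d) == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-9)

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = np.array([1.3, -0.4, 2.2, -3.1, 0.7, 1.9, -2.6, 0.2, 4.0, -1.1])
        assert wilcoxon_signed_rank(d) == pytest.approx(
            scipy_wilcoxon(d, method="exact").pvalue, abs=1e-9
        )

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.zeros(10))

    def test_null_distribution_rarely_significant(self):
        rng = np.random.default_rng(42)
        hits = sum(
            wilcoxon_signed_rank(rng.normal(size=20)) > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_large_sample_normal_branch(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.8, 1.0, size=60)
        p = wilcoxon_signed_rank(d)
        assert p < 1e-4  # clearly shifted


class TestCccProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        x=arrays(np.float64, 8, elements=st.floats(-100, 100)),
        y=arrays(np.float64, 8, elements=st.floats(-100, 100)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_lin_ccc_symmetric_and_bounded(self, x, y):
        if x.var() + y.var() + (x.mean() - y.mean()) ** 2 < 1e-9:
            return  # degenerate, raises by contract
        v = lin_ccc(x, y)
        assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9
        assert v == pytest.approx(lin_ccc(y, x), abs=1e-12)


class TestBootstrap:
    def test_percentile_interval_contains_point_for_stable_stat(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(50, 4)) + rng.normal(size=(50, 1))
        v = occc(data)
        lo, hi = bootstrap_ci(occc, data, reps=500, seed=1)
        assert lo < v < hi
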