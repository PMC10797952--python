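"""Group statistics against hand computations and exhaustive oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mitoredox import (
    aggregate,
    bh_adjust,
    bh_select,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney,
    paired_t,
    pearson,
)


def enumeration_mw_p(a, b):
    """Oracle: exact two-sided Mann–Whitney p by enumerating all labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + 0.5 * sum(
            1 for x in group_a for y in group_b if x == y
        )

    u_obs = u_stat(a, b)
    n12 = len(a) * len(b)
    dev_obs = abs(u_obs - n12 / 2)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if abs(u_stat(ga, gb) - n12 / 2) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestAggregate:
    def _table(self):
        return pd.DataFrame(
            {
                "subject_id": ["m0"] * 4,
                "stack_id": ["s0", "s0", "s1", "s1"],
                "condition": ["basal"] * 4,
                "ratio": [0.9, 1.1, 1.1, 1.3],
            }
        )

    def test_per_stack_then_subject(self):
        per_stack = aggregate(self._table(), "per_stack")
        assert sorted(per_stack["ratio"]) == pytest.approx([1.0, 1.2])
        per_subject = aggregate(self._table(), "per_subject")
        assert per_subject.loc[0, "ratio"] == pytest.approx(1.1)

    def test_idempotent(self):
        once = aggregate(self._table(), "per_subject")
        twice = aggregate(once, "per_subject")
        assert twice["ratio"].tolist() == pytest.approx(once["ratio"].tolist())

    def test_generator_truth_recovered(self, small_scene):
        truths = small_scene.true_ratios
        sem = truths.std(ddof=1) / np.sqrt(len(truths))
        assert abs(truths.mean() - 1.06) < 3 * sem + 1e-9


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.test

    def test_interleaved_groups_exact(self):
        res = mann_whitney([1, 4], [2, 3])
        assert res.statistic == pytest.approx(2.0)  # n1·n2/2
        assert res.p_value == pytest.approx(1.0)

    def test_identical_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (5, 5)])
    def test_exact_p_equals_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        a = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
        b = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), a)
        res = mann_whitney(a, b)
        assert "exact" in res.test
        assert res.p_value == pytest.approx(enumeration_mw_p(a, b), abs=1e-12)


class TestPairedT:
    def test_hand_computation(self):
        # differences (1,2,3): t = 2 / (1/√3) ≈ 3.4641, df = 2
        before = np.array([0.0, 0.0, 0.0])
        after = np.array([1.0, 2.0, 3.0])
        res = paired_t(before, after)
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-9)

    def test_degenerate_constant_differences(self):
        res = paired_t([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert res.degenerate
        assert "constant" in res.note

    def test_sign_symmetry(self):
        rng = np.random.default_rng(5)
        before = rng.normal(1.0, 0.1, 10)
        after = before + rng.normal(0.1, 0.05, 10)
        r1 = paired_t(before, after)
        r2 = paired_t(after, before)
        assert r2.statistic == pytest.approx(-r1.statistic)
        assert r2.p_value == pytest.approx(r1.p_value)


class TestKruskalDunn:
    def test_hand_computed_h(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_identical_groups(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == pytest.approx(0.0)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_wallis([[1], [2]])

    def test_dunn_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, 12) for m in (0.0, 0.5, 1.0, 1.5)]
        for res in dunn_posthoc(groups):
            assert res.adjusted_p >= res.p_value - 1e-15
            assert 0 <= res.p_value <= 1 and res.adjusted_p <= 1


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        res = pearson(x, -x)
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_against_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.0, 3.5, 3.0, 5.0])
        want = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        res = pearson(x, y)
        assert res.r == pytest.approx(want, abs=1e-12)

    def test_constant_input_undefined(self):
        res = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined


def bh_rejection_oracle(p, alpha):
    """Oracle: largest k with p_(k) ≤ k·α/m; reject the k smallest."""
    order = np.argsort(p, kind="stable")
    m = len(p)
    k = 0
    for i, o in enumerate(order, start=1):
        if p[o] <= i * alpha / m:
            k = i
    return set(order[:k].tolist())


class TestBenjaminiHochberg:
    def test_single_p(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_stepup_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
        alpha=st.sampled_from([0.01, 0.05, 0.1, 0.25, 0.5]),
    )
    def test_selection_equals_rejection_set_oracle(self, p, alpha):
        p = np.asarray(p)
        got = set(bh_select(p, threshold=alpha).tolist())
        assert got == bh_rejection_oracle(p, alpha)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(9)
        p = np.sort(rng.random(20))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()
        assert (q >= p - 1e-15).all()

    def test_default_threshold_is_exploratory_fdr(self):
        # display-selection rule: FDR 0.25
        p = np.array([0.001, 0.2, 0.9])
        assert 0 in bh_select(p)
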