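"""Chi-square statistic and greedy table compression."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from succsite.contingency import (
    ContingencyTable,
    chi2_stat,
    compress_table,
    local_chi2_test,
)


def _pearson(pos, neg):
    """Textbook Pearson statistic, independent of the positive-row form."""
    obs = np.array([pos, neg], dtype=float)
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[1] < 2:
        return 0.0
    stat, _, _, _ = chi2_contingency(obs, correction=False)
    return stat


def _naive_compress(pos, neg, alpha, mode, min_groups=2):
    """Brute-force re-implementation: full recomputation via scipy each step."""
    groups = [(i,) for i in range(len(pos))]
    pos, neg = list(map(float, pos)), list(map(float, neg))
    while len(groups) > min_groups:
        r = len(groups)
        pairs = (
            [(i, i + 1) for i in range(r - 1)]
            if mode == "adjacent"
            else [(i, j) for i in range(r) for j in range(i + 1, r)]
        )
        zero = [p for p in pairs if pos[p[0]] + neg[p[0]] == 0
                or pos[p[1]] + neg[p[1]] == 0]
        use = zero or pairs

        def merged_stat(i, j):
            mp, mn = pos[:], neg[:]
            mp[i] += mp[j]; mn[i] += mn[j]
            del mp[j], mn[j]
            return _pearson(mp, mn)

        i, j = max(use, key=lambda p: (merged_stat(*p), (-p[0], -p[1])))
        if zero:
            pval = 1.0
        else:
            table = np.array([[pos[i], pos[j]], [neg[i], neg[j]]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                pval = 1.0
            else:
                _, pval, _, _ = chi2_contingency(table, correction=False)
            if pval < alpha:
                break
        pos[i] += pos[j]; neg[i] += neg[j]
        groups[i] = groups[i] + groups[j]
        del pos[j], neg[j], groups[j]
    return groups


def _random_table(rng, m, allow_zero=False):
    low = 0 if allow_zero else 1
    return (
        rng.integers(low, 30, size=m).astype(float),
        rng.integers(low, 30, size=m).astype(float),
    )


class TestChi2Stat:
    def test_identical_distributions_give_zero(self):
        t = ContingencyTable(("a", "b"), np.array([10, 10]), np.array([10, 10]))
        assert chi2_stat(t) == pytest.approx(0.0)

    def test_perfect_association_equals_n(self):
        t = ContingencyTable(("a", "b"), np.array([10, 0]), np.array([0, 10]))
        assert chi2_stat(t) == pytest.approx(20.0)

    @pytest.mark.parametrize("m", [2, 3, 5, 8])
    def test_equals_textbook_pearson(self, m, rng):
        for _ in range(20):
            pos, neg = _random_table(rng, m, allow_zero=True)
            pos[0] = max(pos[0], 1)  # keep class marginals positive
            neg[0] = max(neg[0], 1)
            t = ContingencyTable(tuple(range(m)), pos, neg)
            assert chi2_stat(t) == pytest.approx(_pearson(pos, neg))

    def test_zero_class_marginal_errors(self):
        t = ContingencyTable(("a", "b"), np.array([0, 0]), np.array([5, 5]))
        with pytest.raises(ValueError, match="marginal"):
            chi2_stat(t)


class TestLocalTest:
    def test_identical_proportions_p_one(self):
        assert local_chi2_test((5, 5), (5, 5)) == pytest.approx(1.0)

    def test_maximal_association_tiny_p(self):
        assert local_chi2_test((10, 0), (0, 10)) < 1e-4

    def test_matches_independent_cdf(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(1, 40, size=4)
            p = local_chi2_test((a, b), (c, d))
            _, p_ref, _, _ = chi2_contingency(
                np.array([[a, b], [c, d]]), correction=False
            )
            assert p == pytest.approx(p_ref)

    def test_zero_marginal_returns_one(self):
        assert local_chi2_test((0, 0), (3, 7)) == 1.0

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            local_chi2_test((-1, 2), (3, 4))


class TestCompression:
    def test_identical_proportion_columns_merge(self):
        t = ContingencyTable(
            ("a", "b", "c", "d"),
            np.array([10, 10, 1, 20]),
            np.array([10, 10, 20, 1]),
        )
        comp = compress_table(t, alpha=0.05, mode="unordered")
        assert comp.r == 3
        assert ("a", "b") in comp.groups

    def test_proportional_table_hits_floor(self):
        t = ContingencyTable(
            ("a", "b", "c"), np.array([10, 20, 30]), np.array([20, 40, 60])
        )
        comp = compress_table(t, alpha=0.05, mode="unordered")
        assert comp.r == 2

    @pytest.mark.parametrize("mode", ["unordered", "adjacent"])
    @pytest.mark.parametrize("m", [3, 4, 5])
    def test_matches_naive_bruteforce(self, mode, m, rng):
        for _ in range(15):
            pos, neg = _random_table(rng, m, allow_zero=True)
            pos[0] = max(pos[0], 1)
            neg[0] = max(neg[0], 1)
            comp = compress_table(
                ContingencyTable(tuple(range(m)), pos, neg), alpha=0.05, mode=mode
            )
            assert list(comp.groups) == _naive_compress(pos, neg, 0.05, mode)

    @pytest.mark.parametrize("mode", ["unordered", "adjacent"])
    def test_invariants_on_random_tables(self, mode, rng):
        for _ in range(15):
            m = int(rng.integers(2, 9))
            pos, neg = _random_table(rng, m, allow_zero=True)
            pos[0] = max(pos[0], 1)
            neg[0] = max(neg[0], 1)
            t = ContingencyTable(tuple(range(m)), pos, neg)
            comp = compress_table(t, alpha=0.05, mode=mode)
            # counts conserved group-wise
            for group, p_col, n_col in zip(
                comp.groups, comp.table.pos_counts, comp.table.neg_counts
            ):
                assert p_col == pytest.approx(sum(pos[k] for k in group))
                assert n_col == pytest.approx(sum(neg[k] for k in group))
            # groups partition the statuses; floor respected
            flat = sorted(k for g in comp.groups for k in g)
            assert flat == list(range(m))
            assert 2 <= comp.r <= m
            # every accepted merge passed its local test
            assert all(p >= 0.05 for _, p in comp.merge_log)
            if mode == "adjacent":  # contiguous runs
                for g in comp.groups:
                    ks = sorted(g)
                    assert ks == list(range(ks[0], ks[-1] + 1))

    def test_zero_columns_never_block(self):
        t = ContingencyTable(
            ("a", "b", "c", "d"),
            np.array([0, 30, 0, 1]),
            np.array([0, 1, 0, 30]),
        )
        comp = compress_table(t, alpha=0.05, mode="adjacent")
        assert comp.r == 2
        flat = sorted(k for g in comp.groups for k in g)
        assert flat == ["a", "b", "c", "d"]
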