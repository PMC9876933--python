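import itertools
import math

import numpy as np
import pytest

from hypnokit import (
    fisher_exact_2x2,
    kruskal_dunn,
    kruskal_wallis_h,
    wilcoxon_rank_sum,
)


def exact_fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


def exact_ranksum_oracle(a, b):
    """Two-sided rank-sum p by enumerating all group assignments.

    Tied cross-pairs count 1/2 toward U. The permutation-null U
    distribution is symmetric about n1*n2/2 (swapping group labels maps U
    to n1*n2 - U), so the two-sided p is the probability of a U at least as
    far from that centre as the observed one.
    """

    def u_stat(ga, gb):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0
                   for x in ga for y in gb)

    pooled = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)
    mean = n1 * len(b) / 2.0
    u_obs = u_stat(a, b)
    dist = []
    for comb in itertools.combinations(range(n), n1):
        chosen = set(comb)
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(n) if i not in chosen]
        dist.append(u_stat(ga, gb))
    tail = sum(1 for u in dist if abs(u - mean) >= abs(u_obs - mean) - 1e-12)
    return tail / len(dist)


class TestKruskalWallis:
    def test_closed_form_on_separated_groups(self):
        h, _ = kruskal_wallis_h([[1, 2, 3], [11, 12, 13], [21, 22, 23]])
        assert h == pytest.approx(7.2)

    def test_matches_rank_formula_on_tie_free_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            sizes = rng.integers(3, 8, size=3)
            data = rng.permutation(np.arange(1.0, sizes.sum() + 1))
            groups = np.split(data, np.cumsum(sizes)[:-1])
            h, _ = kruskal_wallis_h([g.tolist() for g in groups])
            n = sizes.sum()
            ranks = {v: r for r, v in enumerate(sorted(data), start=1)}
            h_formula = (12 / (n * (n + 1))) * sum(
                len(g) * np.mean([ranks[v] for v in g]) ** 2 for g in groups
            ) - 3 * (n + 1)
            assert h == pytest.approx(h_formula)

    def test_label_permutation_invariance(self):
        groups = [[5.0, 1.0, 9.0], [2.0, 7.0], [4.0, 3.0, 8.0]]
        h1, _ = kruskal_wallis_h(groups)
        h2, _ = kruskal_wallis_h(groups[::-1])
        assert h1 == pytest.approx(h2)


class TestKruskalDunn:
    def test_identical_groups_nothing_significant(self):
        g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]}
        res = kruskal_dunn(g)
        assert res.p_omnibus > 0.9
        assert not res.pairwise["significant"].any()

    def test_separated_groups_flagged(self):
        g = {"healthy": [40.0, 42, 44, 41, 43, 45, 46, 39],
             "parkinsonian": [8.0, 9, 7, 10, 8.5, 9.5, 7.5, 8.2],
             "lfs": [38.0, 41, 39, 42, 40, 43, 37, 44]}
        res = kruskal_dunn(g)
        assert res.p_omnibus < 0.01
        table = res.pairwise.set_index(["group_a", "group_b"])
        assert table.loc[("healthy", "parkinsonian"), "significant"]
        assert not table.loc[("healthy", "lfs"), "significant"]

    def test_adjustment_modes_ordering(self):
        g = {"a": [1.0, 2, 3], "b": [4.0, 5, 6], "c": [7.0, 8, 9]}
        p_none = kruskal_dunn(g, adjustment="none").pairwise["p_adjusted"]
        p_holm = kruskal_dunn(g, adjustment="holm").pairwise["p_adjusted"]
        p_bonf = kruskal_dunn(g, adjustment="bonferroni").pairwise["p_adjusted"]
        assert (p_none <= p_holm + 1e-12).all()
        assert (p_holm <= p_bonf + 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1.0], "b": []})


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            exact_fisher_oracle([[5, 0], [0, 5]]))
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            2 / math.comb(10, 5))

    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[3, 3], [3, 3]]) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_matches_enumeration_oracle_all_small_tables(self):
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    for d in range(4):
                        if a + b == 0 or c + d == 0:
                            continue
                        table = [[a, b], [c, d]]
                        assert fisher_exact_2x2(table) == pytest.approx(
                            exact_fisher_oracle(table), abs=1e-10), table


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1.0, 1, 1], [1.0, 1, 1]) == 1.0

    def test_two_vs_two_exact(self):
        assert wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0]) == pytest.approx(1 / 3)

    def test_symmetry(self):
        a, b = [1.0, 5.0, 2.5], [3.0, 4.0, 7.0, 0.5]
        assert wilcoxon_rank_sum(a, b) == pytest.approx(wilcoxon_rank_sum(b, a))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 6))
            pool = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = list(pool[:n1]), list(pool[n1:])
            assert wilcoxon_rank_sum(a, b) == pytest.approx(
                exact_ranksum_oracle(a, b)), (a, b)
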