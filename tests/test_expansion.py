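"""Exact binomial tails, BH adjustment and the expansion call criteria."""

import numpy as np
from fractions import Fraction
import pandas as pd
import pytest
from scipy.special import comb

from camgen.expansion import (GroupPartition, bh_adjust, binomial_group_test,
                              classify_orthogroups, two_species_expansion)
from camgen.io import GeneCountMatrix


def pmf_tail_oracle(k, n, p_frac, upper=True):
    """Direct summation of binomial pmf terms in exact rational arithmetic.

    ``p_frac`` is a Fraction; the tail is the exact integer sum
    sum_i C(n,i) a^i b^(n-i) over c^n with p = a/c, 1-p = b/c, converted
    to float only at the end.
    """
    p_frac = Fraction(p_frac)
    a, c = p_frac.numerator, p_frac.denominator
    b = c - a
    ks = range(k, n + 1) if upper else range(0, k + 1)
    total = sum(comb(n, i, exact=True) * a ** i * b ** (n - i) for i in ks)
    return float(Fraction(total, c ** n))


def _matrix(rows, na=2, nb=2):
    species = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
    return GeneCountMatrix([f"OG{i}" for i in range(len(rows))], species,
                           np.asarray(rows)), \
        GroupPartition(tuple(species[:na]), tuple(species[na:]))


class TestBinomialGroupTest:
    def test_all_genes_in_group_a(self):
        # n=2 genes, both in A; with p = 5/18 the upper tail is p^2
        m = GeneCountMatrix(["OG0"],
                            [f"s{i}" for i in range(18)],
                            [[1, 1] + [0] * 16])
        part = GroupPartition(tuple(f"s{i}" for i in range(5)),
                              tuple(f"s{i}" for i in range(5, 18)))
        stats = binomial_group_test(m, part)
        assert stats.loc["OG0", "p_expand"] == pytest.approx(
            (5 / 18) ** 2, abs=1e-15)
        assert stats.loc["OG0", "p_expand"] == pytest.approx(25 / 324)

    def test_zero_in_group_a(self):
        m = GeneCountMatrix(["OG0"], [f"s{i}" for i in range(18)],
                            [[0] * 5 + [1] * 3 + [0] * 10])
        part = GroupPartition(tuple(f"s{i}" for i in range(5)),
                              tuple(f"s{i}" for i in range(5, 18)))
        stats = binomial_group_test(m, part)
        assert stats.loc["OG0", "p_expand"] == 1.0
        assert stats.loc["OG0", "p_contract"] == pytest.approx(
            (13 / 18) ** 3, abs=1e-15)

    @pytest.mark.parametrize("n,k", [(30, 20), (100, 40), (10_000, 2900)])
    def test_tail_matches_pmf_summation(self, n, k):
        p = Fraction(5, 18)
        m, part = _matrix([[k, 0, n - k, 0]])
        stats = binomial_group_test(m, part)
        # partition p_success = 2/4 here; rebuild with 5/18-like groups
        species = [f"s{i}" for i in range(18)]
        counts = np.zeros((1, 18), dtype=int)
        counts[0, 0], counts[0, 5] = k, n - k
        m = GeneCountMatrix(["OG0"], species, counts)
        part = GroupPartition(tuple(species[:5]), tuple(species[5:]))
        stats = binomial_group_test(m, part)
        assert stats.loc["OG0", "p_expand"] == pytest.approx(
            pmf_tail_oracle(k, n, p, upper=True), abs=1e-12)
        assert stats.loc["OG0", "p_contract"] == pytest.approx(
            pmf_tail_oracle(k, n, p, upper=False), abs=1e-12)

    def test_untestable_rows_dropped(self):
        m, part = _matrix([[0, 0, 0, 0], [1, 0, 1, 0]])
        stats = binomial_group_test(m, part)
        assert list(stats.index) == ["OG1"]

    def test_missing_species_named_in_error(self):
        m, _ = _matrix([[1, 0, 1, 0]])
        part = GroupPartition(("A0", "ghost"), ("B0", "B1"))
        with pytest.raises(KeyError, match="ghost"):
            binomial_group_test(m, part)

    def test_ratio_infinite_when_group_b_empty(self):
        m, part = _matrix([[3, 2, 0, 0]])
        stats = binomial_group_test(m, part)
        assert np.isinf(stats.loc["OG0", "ratio"])


class TestBhAdjust:
    def test_hand_step_up(self):
        # step-up: q_(i) = min over j>=i of m*p_(j)/j, here all collapse to 0.03
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])

    def test_matches_step_up_definition_on_random_input(self, rng):
        p = rng.uniform(size=200)
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), oracle, atol=1e-14)

    def test_nan_is_hard_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])


class TestClassify:
    def _stats(self, **kw):
        base = dict(S_An=10, S_Bn=2, n=12, k_contrib_A=5, k_contrib_B=2,
                    ratio=4.2, p_expand=0.001, p_contract=0.999)
        base.update(kw)
        return pd.DataFrame([base], index=["OG0"])

    def test_all_criteria_met(self):
        out = classify_orthogroups(self._stats())
        assert bool(out.loc["OG0", "expanded"])

    def test_contribution_criterion_blocks_call(self):
        out = classify_orthogroups(self._stats(k_contrib_A=2))
        assert not out.loc["OG0", "expanded"]

    def test_expanded_and_contracted_disjoint(self, rng):
        n = 300
        df = pd.DataFrame({
            "S_An": rng.integers(0, 30, n), "S_Bn": rng.integers(0, 30, n),
            "k_contrib_A": rng.integers(0, 6, n),
            "k_contrib_B": rng.integers(0, 14, n),
            "ratio": rng.uniform(0, 5, n),
            "p_expand": rng.uniform(size=n),
            "p_contract": rng.uniform(size=n)})
        df["n"] = df.S_An + df.S_Bn
        out = classify_orthogroups(df)
        assert not (out["expanded"] & out["contracted"]).any()

    def test_matches_naive_row_filter(self, rng):
        n = 500
        df = pd.DataFrame({
            "S_An": rng.integers(0, 30, n), "S_Bn": rng.integers(0, 30, n),
            "k_contrib_A": rng.integers(0, 6, n),
            "k_contrib_B": rng.integers(0, 14, n),
            "ratio": rng.uniform(0, 3, n),
            "p_expand": rng.uniform(size=n) ** 3,
            "p_contract": rng.uniform(size=n) ** 3})
        df["n"] = df.S_An + df.S_Bn
        out = classify_orthogroups(df, 0.05, 3, 7)
        for _, row in out.iterrows():
            exp = (row.q_expand < 0.05 and row.k_contrib_A >= 3
                   and row.ratio > 1)
            con = (row.q_contract < 0.05 and row.k_contrib_B >= 7
                   and row.ratio < 1)
            assert bool(row.expanded) == exp and bool(row.contracted) == con


class TestTwoSpeciesExpansion:
    def _m(self, rows):
        return GeneCountMatrix([f"OG{i}" for i in range(len(rows))],
                               ["cr", "vv", "at"], np.asarray(rows))

    def test_expanded(self):
        m = self._m([[10, 0, 0]])
        p = pd.Series({"OG0": 0.01})
        assert two_species_expansion(m, p, "cr") == ["OG0"]

    def test_boundary_mean_is_strict(self):
        m = self._m([[3, 3, 3]])
        p = pd.Series({"OG0": 0.001})
        assert two_species_expansion(m, p, "cr") == []

    def test_missing_pvalues_hard_error(self):
        m = self._m([[1, 2, 3]])
        with pytest.raises(KeyError):
            two_species_expansion(m, pd.Series(dtype=float), "cr")

    def test_matches_naive_filter_on_random_rows(self, rng):
        rows = rng.integers(0, 12, size=(500, 3))
        m = self._m(rows)
        pv = pd.Series(rng.uniform(size=500), index=m.orthogroup_ids)
        calls = set(two_species_expansion(m, pv, "vv", alpha=0.1))
        naive = {og for i, og in enumerate(m.orthogroup_ids)
                 if pv[og] < 0.1 and rows[i, 1] > rows[i].mean()}
        assert calls == naive
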