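"""Filter-statistic unit and property tests.

The Mendelian-error and HWE tests check the implementations against
independent oracles: brute-force enumeration of the one-allele-from-
each-parent rule, and an exact-rational-arithmetic enumeration of the
heterozygote-count null distribution.
"""

import itertools
import math
from fractions import Fraction
from math import factorial

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varforest.io import Sex, Pedigree
from varforest.qc_stats import (abhet, genotype_consistent, hwe_exact_p,
                                _het_count_null_probs, maf,
                                mendel_error_rate, missing_rate)
from .conftest import make_record, make_trio_pedigree


class TestMissingRate:
    def test_counts_missing_alleles(self):
        v = make_record([(0, 1), (0, 0), None, (1, 1)])
        assert missing_rate(v) == pytest.approx(0.25)

    def test_bounds(self):
        assert missing_rate(make_record([(0, 1), (1, 1)])) == 0.0
        assert missing_rate(make_record([None, None])) == 1.0


# ---------------------------------------------------------------------------
# Mendelian errors


def oracle_consistent(child, father, mother):
    """Brute force: enumerate which parental allele goes to the child."""
    for fa in father:
        for mo in mother:
            if sorted((fa, mo)) == sorted(child):
                return True
    return False


class TestMendel:
    def test_all_27_ordered_trio_combinations(self):
        """15 of the 27 ordered biallelic combos are consistent, 12 are errors."""
        gts = [(0, 0), (0, 1), (1, 1)]
        n_ok = 0
        for child, father, mother in itertools.product(gts, repeat=3):
            expect = oracle_consistent(child, father, mother)
            assert genotype_consistent(child, father, mother) == expect
            n_ok += expect
        assert n_ok == 15

    def test_impossible_child_allele(self):
        ped = make_trio_pedigree(1)
        v = make_record([(0, 0), (0, 0), (0, 1)])
        idx = {"fa0": 0, "mo0": 1, "ch0": 2}
        assert mendel_error_rate(v, ped, idx) == 1.0

    def test_het_by_het_permits_everything(self):
        ped = make_trio_pedigree(1)
        idx = {"fa0": 0, "mo0": 1, "ch0": 2}
        for child in [(0, 0), (0, 1), (1, 1)]:
            v = make_record([(0, 1), (0, 1), child])
            assert mendel_error_rate(v, ped, idx) == 0.0

    def test_missing_member_makes_trio_non_evaluable(self):
        ped = make_trio_pedigree(1)
        idx = {"fa0": 0, "mo0": 1, "ch0": 2}
        v = make_record([None, (0, 0), (1, 1)])
        assert math.isnan(mendel_error_rate(v, ped, idx))

    def test_non_autosome_returns_na(self):
        ped = make_trio_pedigree(1)
        idx = {"fa0": 0, "mo0": 1, "ch0": 2}
        v = make_record([(0, 0), (0, 0), (1, 1)], chrom="X")
        assert math.isnan(mendel_error_rate(v, ped, idx))

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_oracle_on_random_multi_trio_variants(self, data):
        n_trios = data.draw(st.integers(1, 10))
        ped = make_trio_pedigree(n_trios)
        idx = {}
        gts = []
        gt_strat = st.one_of(st.none(), st.tuples(st.integers(0, 1), st.integers(0, 1)))
        for f in range(n_trios):
            for who in ("fa", "mo", "ch"):
                idx[f"{who}{f}"] = len(gts)
                gts.append(data.draw(gt_strat))
        v = make_record(gts)
        got = mendel_error_rate(v, ped, idx)
        n_eval = n_err = 0
        for f in range(n_trios):
            fa, mo, ch = gts[3 * f], gts[3 * f + 1], gts[3 * f + 2]
            if None in (fa, mo, ch):
                continue
            n_eval += 1
            n_err += not oracle_consistent(ch, fa, mo)
        if n_eval == 0:
            assert math.isnan(got)
        else:
            assert got == pytest.approx(n_err / n_eval)
            assert 0.0 <= got <= 1.0


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_oracle(nrr, nra, naa):
    """Exact rational enumeration of the heterozygote-count null."""
    n = nrr + nra + naa
    rare = 2 * min(nrr, naa) + nra
    common = 2 * n - rare

    def prob(h):
        homr = (rare - h) // 2
        homc = n - h - homr
        return (Fraction(factorial(n),
                         factorial(homr) * factorial(h) * factorial(homc))
                * Fraction(2 ** h * factorial(rare) * factorial(common),
                           factorial(2 * n)))

    probs = {h: prob(h) for h in range(rare % 2, min(rare, common) + 1, 2)}
    assert sum(probs.values()) == 1
    obs = probs[nra]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHwe:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(10, 0, 0) == 1.0

    def test_single_minor_allele_is_one(self):
        assert hwe_exact_p(1, 1, 0) == 1.0

    def test_enumeration_example(self):
        assert hwe_exact_p(1, 3, 1) == pytest.approx(hwe_oracle(1, 3, 1), abs=1e-12)

    @pytest.mark.parametrize("nrr,nra,naa", [
        (5, 2, 5), (0, 4, 8), (7, 0, 7), (3, 3, 3), (12, 1, 0),
    ])
    def test_matches_rational_oracle(self, nrr, nra, naa):
        assert hwe_exact_p(nrr, nra, naa) == pytest.approx(
            hwe_oracle(nrr, nra, naa), abs=1e-10)

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=150, deadline=None)
    def test_symmetry_under_hom_swap(self, a, b, c):
        if a + b + c == 0:
            assert math.isnan(hwe_exact_p(a, b, c))
        else:
            assert hwe_exact_p(a, b, c) == hwe_exact_p(c, b, a)
            assert 0.0 < hwe_exact_p(a, b, c) <= 1.0

    @given(st.integers(1, 50), st.data())
    @settings(max_examples=100, deadline=None)
    def test_null_probabilities_sum_to_one(self, n, data):
        rare = data.draw(st.integers(0, n))  # rare <= n <= 2n - rare
        probs = _het_count_null_probs(rare, n)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 0)


# ---------------------------------------------------------------------------
# ABHet and MAF


class TestAbhet:
    def test_perfect_balance(self):
        v = make_record([(0, 1)], ad=[(5, 5)])
        assert abhet(v) == pytest.approx(0.5)

    def test_pooled_not_averaged(self):
        v = make_record([(0, 1), (0, 1)], ad=[(7, 3), (3, 7)])
        assert abhet(v) == pytest.approx(0.5)

    def test_boundary_point_seven(self):
        v = make_record([(0, 1), (0, 1)], ad=[(9, 1), (5, 5)])
        assert abhet(v) == pytest.approx(0.7)

    def test_non_het_ad_ignored(self):
        v1 = make_record([(0, 1), (0, 0)], ad=[(6, 4), (10, 0)])
        v2 = make_record([(0, 1), (0, 0)], ad=[(6, 4), (0, 999)])
        assert abhet(v1) == abhet(v2) == pytest.approx(0.6)

    def test_sample_order_invariance(self):
        v1 = make_record([(0, 1), (0, 1), (1, 1)], ad=[(9, 1), (2, 8), (0, 30)])
        v2 = make_record([(0, 1), (1, 1), (0, 1)], ad=[(2, 8), (0, 30), (9, 1)])
        assert abhet(v1) == pytest.approx(abhet(v2))

    def test_altalt_het_excluded(self):
        # 1/2 carries no reference reads to balance; only 0/1 contributes
        v = make_record([(1, 2), (0, 1)], alts=("G", "T"),
                        ad=[(0, 5, 5), (6, 4, 0)])
        assert abhet(v) == pytest.approx(0.6)

    def test_no_het_gives_na(self):
        v = make_record([(0, 0), (1, 1)], ad=[(9, 0), (0, 9)])
        assert math.isnan(abhet(v))

    def test_chrx_uses_females_only(self):
        ped = Pedigree([("m", None, None, Sex.MALE), ("f", None, None, Sex.FEMALE)])
        idx = {"m": 0, "f": 1}
        v = make_record([(0, 1), (0, 1)], chrom="X", ad=[(9, 1), (5, 5)])
        assert abhet(v, ped, idx) == pytest.approx(0.5)   # male excluded
        assert abhet(v) == pytest.approx(0.7)             # no pedigree: all


class TestMaf:
    def test_basic(self):
        assert maf(make_record([(0, 0), (0, 0), (0, 1)])) == pytest.approx(1 / 6)

    def test_half(self):
        assert maf(make_record([(0, 1), (0, 1)])) == pytest.approx(0.5)

    def test_ref_can_be_minor(self):
        assert maf(make_record([(1, 1), (1, 1), (0, 1)])) == pytest.approx(1 / 6)

    def test_missing_excluded(self):
        assert maf(make_record([None, (0, 1)])) == pytest.approx(0.5)

    def test_all_missing_na(self):
        assert math.isnan(maf(make_record([None, None])))
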