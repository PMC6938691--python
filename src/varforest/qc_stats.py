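"""Per-variant filter statistics.

The four hard-filter statistics used by the first QC stage — genotype
missing rate, Mendelian error rate over pedigree trios, the exact test
of Hardy-Weinberg equilibrium, and the pooled allele balance of
heterozygous calls (ABHet) — plus the minor allele frequency used for
the rare/common reporting split.

Conventions
-----------
* NA is represented as ``math.nan``; it arises only in the documented
  degenerate cases (no evaluable trios, all-missing site, no qualifying
  het sample).
* The HWE test pools all alternate alleles into one class on
  multi-allelic sites (ref vs non-ref), matching the semantics ABHet
  already uses; the exact test itself is defined biallelically.
* Mendelian errors are computed for autosomes only; sex chromosomes and
  mitochondria return NA rather than applying diploid trio logic to
  hemizygous calls.
* ABHet heterozygotes are ref/alt hets only (exactly one allele index 0,
  one nonzero); alt/alt hets such as 1/2 carry no reference reads to
  balance.  On chromosome X only females contribute (all samples when no
  pedigree is supplied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import MISSING, Pedigree, Sex, VariantRecord, is_autosome, is_chrx

NA = math.nan


def is_na(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass
class VariantStats:
    """Filter statistics plus classifier features for one site."""

    missing_rate: float
    mendel_error_rate: float  # NA without a pedigree / evaluable trios
    hwe_p: float
    abhet: float
    maf: float
    mean_dp: float = NA
    sd_dp: float = NA
    outlier_dp: float = NA
    mean_gq: float = NA
    sd_gq: float = NA
    outlier_gq: float = NA
    gc: float = NA


def missing_rate(v: VariantRecord) -> float:
    """Fraction of missing alleles: (# missing alleles) / (2 * n_samples)."""
    if v.n_samples == 0:
        raise ValueError("variant has no samples")
    return float((v.genotypes == MISSING).sum()) / (2 * v.n_samples)


# ---------------------------------------------------------------------------
# Mendelian errors


def genotype_consistent(child: tuple[int, int], father: tuple[int, int],
                        mother: tuple[int, int]) -> bool:
    """Can the child's genotype be formed by one allele from each parent?"""
    c1, c2 = child
    return ((c1 in father and c2 in mother) or (c2 in father and c1 in mother))


def mendel_error_rate(v: VariantRecord, ped: Pedigree | None,
                      sample_index: dict[str, int] | None = None) -> float:
    """Mendelian errors / evaluable trios; NA without pedigree or trios.

    A trio is evaluable iff all three members are present in the VCF and
    fully genotyped.  Non-autosomal sites return NA.
    """
    if ped is None:
        return NA
    if not is_autosome(v.chrom):
        return NA
    if sample_index is None:
        sample_index = {}
    gts = v.genotypes
    n_eval = 0
    n_err = 0
    for trio in ped.trios():
        try:
            ci, fi, mi = (sample_index[trio.child], sample_index[trio.father],
                          sample_index[trio.mother])
        except KeyError:
            continue  # member absent from VCF: trio not evaluable
        child = (int(gts[ci, 0]), int(gts[ci, 1]))
        father = (int(gts[fi, 0]), int(gts[fi, 1]))
        mother = (int(gts[mi, 0]), int(gts[mi, 1]))
        if MISSING in child or MISSING in father or MISSING in mother:
            continue
        n_eval += 1
        if not genotype_consistent(child, father, mother):
            n_err += 1
    if n_eval == 0:
        return NA
    return n_err / n_eval


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact test of Hardy-Weinberg equilibrium on biallelic genotype counts.

    Conditional on the observed allele counts, the null distribution of
    the heterozygote count is computed over all attainable values (those
    sharing the parity of the minor-allele count); the p-value is the
    total null probability of heterozygote counts at most as probable as
    the observed one.  The plain exact test is used (no mid-p
    correction).  Returns NA when no genotypes were observed.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        return NA
    rare = 2 * min(n_homref, n_homalt) + n_het  # minor allele count
    probs = _het_count_null_probs(rare, n)
    obs = probs.get(n_het)
    if obs is None:  # defensive: observed het count must be attainable
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = sum(pr for pr in probs.values() if pr <= obs * (1 + 1e-12))
    return min(1.0, p)


def _het_count_null_probs(rare: int, n: int) -> dict[int, float]:
    """Null P(het count) given ``rare`` minor alleles among ``n`` diploids.

    Built by the standard ratio recurrence from the mode outward, then
    normalised; numerically stable for any n seen in practice.
    """
    if rare == 0:
        return {0: 1.0}
    # attainable het counts share the parity of the minor allele count
    lo = rare % 2
    hi = min(rare, 2 * n - rare)
    # unnormalised probabilities via the recurrence
    #   P(h) / P(h+2) = (h+2)(h+1) / ((r-h)/2 * (n - (r+h)/2 - ... ))
    mid = rare * (2 * n - rare) / (2 * n)  # expected het count
    mid = int(mid)
    if (mid % 2) != lo:
        mid += 1
    mid = min(max(mid, lo), hi)
    probs = {mid: 1.0}
    # going down: P(h-2) = P(h) * h*(h-1) / (4 * hr_up * ha_up)
    h = mid
    homr = (rare - h) // 2          # minor-class homozygotes at h
    homc = n - h - homr             # major-class homozygotes at h
    hr, hc = homr, homc
    cur = 1.0
    while h > lo:
        cur = cur * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        h -= 2
        hr += 1
        hc += 1
        probs[h] = cur
    # going up: P(h+2) = P(h) * 4*hr*hc / ((h+2)*(h+1))
    h = mid
    hr, hc = homr, homc
    cur = 1.0
    while h + 2 <= hi:
        cur = cur * 4.0 * hr * hc / ((h + 2.0) * (h + 1.0))
        h += 2
        hr -= 1
        hc -= 1
        probs[h] = cur
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def genotype_counts(v: VariantRecord) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts, pooling all alt alleles as one class."""
    g = v.genotypes
    called = (g[:, 0] != MISSING) & (g[:, 1] != MISSING)
    a = g[called] > 0  # alt indicator per allele
    n_alt = a.sum(axis=1)
    return int((n_alt == 0).sum()), int((n_alt == 1).sum()), int((n_alt == 2).sum())


def hwe_p_of_record(v: VariantRecord) -> float:
    """HWE exact p on ref-vs-pooled-alt genotype counts; NA if all missing."""
    nrr, nra, naa = genotype_counts(v)
    if nrr + nra + naa == 0:
        return NA
    return hwe_exact_p(nrr, nra, naa)


# ---------------------------------------------------------------------------
# Allele balance of heterozygotes


def abhet(v: VariantRecord, ped: Pedigree | None = None,
          sample_index: dict[str, int] | None = None) -> float:
    """Pooled reference-read fraction over ref/alt-heterozygous samples.

    sum(AD[0]) / sum(total AD) over included het samples.  On chrX only
    female samples are included (all samples when no pedigree is given).
    NA when no qualifying het sample has usable AD.
    """
    if v.ad is None:
        return NA
    g = v.genotypes
    het = ((g == 0).sum(axis=1) == 1) & ((g > 0).sum(axis=1) == 1)
    if is_chrx(v.chrom) and ped is not None:
        if sample_index is None:
            sample_index = {}
        female = np.zeros(v.n_samples, dtype=bool)
        for iid, _, _, sex in ped.individuals:
            if sex is Sex.FEMALE and iid in sample_index:
                female[sample_index[iid]] = True
        het &= female
    if not het.any():
        return NA
    ad = v.ad[het]
    usable = (ad >= 0).all(axis=1)
    ad = ad[usable]
    total = ad.sum()
    if len(ad) == 0 or total <= 0:
        return NA
    return float(ad[:, 0].sum()) / float(total)


def maf(v: VariantRecord) -> float:
    """Minor allele frequency, ref vs pooled alt, over non-missing alleles."""
    g = v.genotypes
    called = g != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        return NA
    f_alt = float((g[called] > 0).sum()) / n_called
    return min(f_alt, 1.0 - f_alt)


def compute_filter_stats(v: VariantRecord, ped: Pedigree | None = None,
                         sample_index: dict[str, int] | None = None) -> VariantStats:
    """All four filter statistics plus MAF for one variant."""
    return VariantStats(
        missing_rate=missing_rate(v),
        mendel_error_rate=mendel_error_rate(v, ped, sample_index),
        hwe_p=hwe_p_of_record(v),
        abhet=abhet(v, ped, sample_index),
        maf=maf(v),
    )
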