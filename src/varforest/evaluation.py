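"""Quality-assessment metrics for a labelled variant set.

Variant-level: SNV/indel counts, known/novel split against a dbSNP-style
resource, multi-allelic fraction, mean missing and Mendelian-error
rates, mean genotype discordance against microarray data, rare-variant
fraction (MAF < 0.03).  Sample-level: per-individual SNV/indel carriage,
novel SNVs, singletons, and Ti/Tv over known and novel SNVs.

Ti/Tv background: transitions (A<->G, C<->T) outnumber transversions
roughly 2:1 genome-wide in humans; random false-positive calls dilute
the ratio toward 0.5, so a depressed Ti/Tv flags a contaminated call
set.  Mitochondrial sites are excluded by default because mtDNA
substitution spectra are strongly transition-biased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (KnownSites, MicroarrayGenotypes, Pedigree, VariantRecord,
                 is_mito, MISSING)
from .qc_stats import maf, mendel_error_rate, missing_rate

NA = math.nan

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(ref: str, alt: str) -> bool:
    """True for A<->G or C<->T single-base substitutions."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("transition/transversion defined for SNVs only")
    return frozenset((ref.upper(), alt.upper())) in _TRANSITIONS


def titv_ratio(records: Sequence[VariantRecord], include_mito: bool = False) -> float:
    """Variant-level Ti/Tv: each alt allele of each SNV counted once.

    NA when the transversion count is zero.  Raises on indel input.
    """
    ti = tv = 0
    for v in records:
        if not v.is_snv:
            raise ValueError(f"indel passed to Ti/Tv at {v.chrom}:{v.pos}")
        if is_mito(v.chrom) and not include_mito:
            continue
        for alt in v.alts:
            if is_transition(v.ref, alt):
                ti += 1
            else:
                tv += 1
    return ti / tv if tv else NA


def titv_per_sample(records: Sequence[VariantRecord], samples: Sequence[str],
                    known: KnownSites | None = None,
                    include_mito: bool = False) -> pd.DataFrame:
    """Per-individual Ti/Tv over carried SNVs, split known/novel.

    An individual "carries" a site when its genotype holds at least one
    alternate allele; each distinct carried alt allele counts once.
    Columns: titv_known, titv_novel (NA where known-sites data or a
    transversion denominator is absent).
    """
    ti = np.zeros((len(samples), 2), dtype=int)  # columns: known, novel
    tv = np.zeros((len(samples), 2), dtype=int)
    for v in records:
        if not v.is_snv or (is_mito(v.chrom) and not include_mito):
            continue
        for ai, alt in enumerate(v.alts, start=1):
            carriers = (v.genotypes == ai).any(axis=1)
            if not carriers.any():
                continue
            col = 0 if (known is not None and known.contains(v.chrom, v.pos, v.ref, alt)) else 1
            tgt = ti if is_transition(v.ref, alt) else tv
            tgt[carriers, col] += 1
    out = pd.DataFrame(index=list(samples))
    with np.errstate(divide="ignore", invalid="ignore"):
        out["titv_known"] = np.where(tv[:, 0] > 0, ti[:, 0] / np.maximum(tv[:, 0], 1), NA)
        out["titv_novel"] = np.where(tv[:, 1] > 0, ti[:, 1] / np.maximum(tv[:, 1], 1), NA)
    if known is None:
        out["titv_known"] = NA
    return out


def genotype_discordance(v: VariantRecord, chip: MicroarrayGenotypes,
                         samples: Sequence[str]) -> float:
    """Fraction of samples whose unordered allele pair differs between
    sequencing and microarray, over samples non-missing in both; NA when
    no sample is comparable or the site is absent from the chip."""
    if not chip.has_site(v.chrom, v.pos):
        return NA
    alleles = [v.ref] + list(v.alts)
    n_cmp = n_dis = 0
    for i, sample in enumerate(samples):
        chip_gt = chip.get(sample, v.chrom, v.pos)
        if chip_gt is None:
            continue
        a, b = int(v.genotypes[i, 0]), int(v.genotypes[i, 1])
        if a == MISSING or b == MISSING:
            continue
        seq_gt = tuple(sorted((alleles[a], alleles[b])))
        n_cmp += 1
        if seq_gt != chip_gt:
            n_dis += 1
    return n_dis / n_cmp if n_cmp else NA


def known_novel_split(records: Iterable[VariantRecord],
                      known: KnownSites) -> tuple[int, int, float]:
    """(known count, novel count, known %) against the known-sites list."""
    n_known = n_novel = 0
    for v in records:
        if known.contains_record(v):
            n_known += 1
        else:
            n_novel += 1
    total = n_known + n_novel
    return n_known, n_novel, (100.0 * n_known / total if total else NA)


def _mean_ignoring_na(values: list[float]) -> float:
    vals = [x for x in values if not math.isnan(x)]
    return float(np.mean(vals)) if vals else NA


@dataclass
class MetricsReport:
    """Variant-level and sample-level quality metrics for one call set."""

    variant_level: dict = field(default_factory=dict)
    sample_level: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            return x
        return {
            "variant_level": {k: clean(v) for k, v in self.variant_level.items()},
            "sample_level": self.sample_level.where(self.sample_level.notna(), None)
                                             .to_dict(orient="index"),
        }


def summarize(records: Sequence[VariantRecord], samples: Sequence[str],
              ped: Pedigree | None = None,
              chip: MicroarrayGenotypes | None = None,
              known: KnownSites | None = None,
              rare_maf: float = 0.03) -> MetricsReport:
    """Assemble the metrics report for a labelled set of variants.

    Optional resources may be absent; the metrics that need them are NA.
    """
    sample_index = {s: i for i, s in enumerate(samples)}
    snvs = [v for v in records if v.is_snv]
    indels = [v for v in records if not v.is_snv]

    vl: dict = {}
    vl["n_snv"] = len(snvs)
    vl["n_indel"] = len(indels)
    vl["n_multiallelic_snv"] = sum(1 for v in snvs if v.is_multiallelic)
    vl["pct_multiallelic_snv"] = (100.0 * vl["n_multiallelic_snv"] / len(snvs)
                                  if snvs else NA)
    if known is not None:
        k, nov, pct = known_novel_split(snvs, known)
        vl["n_known_snv"], vl["n_novel_snv"], vl["pct_known_snv"] = k, nov, pct
    else:
        vl["n_known_snv"] = vl["n_novel_snv"] = None
        vl["pct_known_snv"] = NA
    vl["mean_missing_rate"] = _mean_ignoring_na([missing_rate(v) for v in records])
    vl["mean_mendel_error_rate"] = _mean_ignoring_na(
        [mendel_error_rate(v, ped, sample_index) for v in records]) if ped else NA
    vl["mean_discordance"] = (_mean_ignoring_na(
        [genotype_discordance(v, chip, samples) for v in snvs]) if chip else NA)
    mafs = [maf(v) for v in records]
    mafs = [m for m in mafs if not math.isnan(m)]
    vl["rare_fraction"] = (sum(1 for m in mafs if m < rare_maf) / len(mafs)
                           if mafs else NA)
    try:
        vl["titv"] = titv_ratio(snvs)
    except ValueError:
        vl["titv"] = NA
    if known is not None:
        vl["titv_known"] = titv_ratio([v for v in snvs if known.contains_record(v)])
        vl["titv_novel"] = titv_ratio([v for v in snvs if not known.contains_record(v)])
    else:
        vl["titv_known"] = vl["titv_novel"] = NA

    # -- sample level -----------------------------------------------------
    n = len(samples)
    n_snv_carried = np.zeros(n, dtype=int)
    n_novel_carried = np.zeros(n, dtype=int)
    n_singleton = np.zeros(n, dtype=int)
    n_indel_carried = np.zeros(n, dtype=int)
    for v in records:
        g = v.genotypes
        carriers = (g > 0).any(axis=1)
        if v.is_snv:
            n_snv_carried[carriers] += 1
            if known is not None and not known.contains_record(v):
                n_novel_carried[carriers] += 1
            # singleton: the only alt allele at the site sits in one individual
            if (g > 0).sum() == 1:
                n_singleton[carriers] += 1
        else:
            n_indel_carried[carriers] += 1
    sl = pd.DataFrame(index=list(samples))
    sl["n_snv"] = n_snv_carried
    sl["n_novel_snv"] = n_novel_carried if known is not None else pd.NA
    sl["n_singletons"] = n_singleton
    sl["n_indel"] = n_indel_carried
    titv_df = titv_per_sample(snvs, samples, known=known)
    sl["titv_known"] = titv_df["titv_known"]
    sl["titv_novel"] = titv_df["titv_novel"]
    return MetricsReport(variant_level=vl, sample_level=sl)
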