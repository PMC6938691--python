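"""Readers and writers for the formats the QC pipeline touches.

VCF (via cyvcf2), PED pedigrees, known-sites lists, microarray genotype
tables, and the label/probability output.  Everything is normalised into
the in-memory types used by the statistics and classifier layers:
genotypes as small integer arrays with ``-1`` for missing, DP/GQ as int
arrays with ``-1`` for missing, AD as a 2-D array or ``None``.

Coordinates are 1-based inclusive throughout (VCF convention).
Chromosome names are matched exactly after stripping an optional ``chr``
prefix, consistently across VCF, FASTA, known-sites and microarray
inputs.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

#: sentinel cyvcf2/htslib uses for absent integer FORMAT values
_INT_SENTINEL = -2147483648 + 10  # anything this negative is "no value"


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix so naming schemes interoperate."""
    return name[3:] if name.lower().startswith("chr") else name


AUTOSOME_EXCLUDED = {"X", "Y", "MT", "M"}


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom).upper() not in AUTOSOME_EXCLUDED


def is_chrx(chrom: str) -> bool:
    return normalize_chrom(chrom).upper() == "X"


def is_mito(chrom: str) -> bool:
    return normalize_chrom(chrom).upper() in {"MT", "M"}


class Sex(Enum):
    MALE = 1
    FEMALE = 2
    UNKNOWN = 0


@dataclass
class VariantRecord:
    """One VCF site with per-sample genotype, DP, GQ and AD.

    ``genotypes`` is an ``(n_samples, 2)`` int16 array of allele indices
    with ``-1`` for a missing allele.  ``dp``/``gq`` are int32 arrays with
    ``-1`` for missing.  ``ad`` is ``(n_samples, 1 + n_alt)`` with ``-1``
    for missing, or ``None`` when the field is absent at the site.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    genotypes: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad: np.ndarray | None = None
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.alts:
            raise ValueError("at least one alternate allele required")
        n_alleles = 1 + len(self.alts)
        if self.genotypes.max(initial=-1) >= n_alleles:
            raise ValueError("genotype allele index out of range")
        if self.ad is not None and self.ad.shape[1] != n_alleles:
            raise ValueError("AD width must equal 1 + n_alt")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    @property
    def is_snv(self) -> bool:
        """True iff ref and every alt are single bases."""
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    def key(self) -> tuple[str, int, str, str]:
        return (normalize_chrom(self.chrom), self.pos, self.ref, ",".join(self.alts))


@dataclass(frozen=True)
class Trio:
    child: str
    father: str
    mother: str


@dataclass
class Pedigree:
    """PED-style pedigree: individuals with optional parents and sex."""

    individuals: list[tuple[str, str | None, str | None, Sex]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i[0] for i in self.individuals]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate individual id in pedigree")

    @property
    def ids(self) -> list[str]:
        return [i[0] for i in self.individuals]

    def sex_of(self, individual: str) -> Sex:
        for iid, _, _, sex in self.individuals:
            if iid == individual:
                return sex
        return Sex.UNKNOWN

    def trios(self) -> list[Trio]:
        """Child/father/mother triples where both parents are declared."""
        declared = set(self.ids)
        out = []
        for iid, father, mother, _ in self.individuals:
            if father in declared and mother in declared:
                out.append(Trio(child=iid, father=father, mother=mother))
        return out


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited PED file (fam, id, father, mother, sex, pheno).

    Sex code 1 -> MALE, 2 -> FEMALE, anything else UNKNOWN.  A parent id
    of ``0`` (or one absent from the file) leaves the individual a
    founder on that side; no trio is formed for it.
    """
    individuals: list[tuple[str, str | None, str | None, Sex]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED line has {len(parts)} columns, need >= 6: {line!r}")
            _, iid, father, mother, sex_code, _ = parts[:6]
            sex = {"1": Sex.MALE, "2": Sex.FEMALE}.get(sex_code, Sex.UNKNOWN)
            individuals.append(
                (iid, None if father == "0" else father, None if mother == "0" else mother, sex)
            )
    return Pedigree(individuals)


class KnownSites:
    """Membership test for a known-variants resource (dbSNP-style).

    Exact ``(chrom, pos, ref, alt)`` lookup by default, with an optional
    positional ``(chrom, pos)`` fallback.  Duplicate entries collapse.
    """

    def __init__(self, position_fallback: bool = False) -> None:
        self._full: set[tuple[str, int, str, str]] = set()
        self._pos: set[tuple[str, int]] = set()
        self.position_fallback = position_fallback

    def add(self, chrom: str, pos: int, ref: str | None = None, alt: str | None = None) -> None:
        chrom = normalize_chrom(chrom)
        self._pos.add((chrom, pos))
        if ref is not None and alt is not None:
            self._full.add((chrom, pos, ref, alt))

    def __len__(self) -> int:
        return len(self._pos)

    def contains(self, chrom: str, pos: int, ref: str | None = None, alt: str | None = None) -> bool:
        chrom = normalize_chrom(chrom)
        if self.position_fallback or ref is None or alt is None:
            return (chrom, pos) in self._pos
        return (chrom, pos, ref, alt) in self._full

    def contains_record(self, rec: VariantRecord) -> bool:
        """A multi-allelic record is known iff any alt allele is known."""
        return any(self.contains(rec.chrom, rec.pos, rec.ref, alt) for alt in rec.alts)


def read_known_sites(path: str | Path, position_fallback: bool = False) -> KnownSites:
    """Load known sites from a VCF or a TSV.

    TSV layouts accepted: ``chrom pos`` (positional only),
    ``chrom pos id`` (positional only), ``chrom pos ref alt`` and
    ``chrom pos id ref alt``.
    """
    path = Path(path)
    ks = KnownSites(position_fallback=position_fallback)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        for rec in VCF(str(path)):
            for alt in rec.ALT or []:
                ks.add(rec.CHROM, rec.POS, rec.REF, alt)
        return ks
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) >= 5:
                chrom, pos, _, ref, alt = parts[:5]
            elif len(parts) == 4:
                chrom, pos, ref, alt = parts
            elif len(parts) >= 2:
                chrom, pos, ref, alt = parts[0], parts[1], None, None
            else:
                continue
            for a in (alt.split(",") if alt else [None]):
                ks.add(chrom, int(pos), ref, a)
    return ks


class MicroarrayGenotypes:
    """Chip genotypes: (sample, chrom, pos) -> unordered base pair.

    Only biallelic SNV sites; genotypes are stored as sorted base tuples
    (e.g. ``("A", "G")``) so strand-agnostic unordered comparison is
    direct.
    """

    def __init__(self) -> None:
        self._gt: dict[tuple[str, str, int], tuple[str, str]] = {}
        self._sites: set[tuple[str, int]] = set()

    def set(self, sample: str, chrom: str, pos: int, a1: str, a2: str) -> None:
        key = (sample, normalize_chrom(chrom), pos)
        self._gt[key] = tuple(sorted((a1, a2)))  # type: ignore[assignment]
        self._sites.add((normalize_chrom(chrom), pos))

    def get(self, sample: str, chrom: str, pos: int) -> tuple[str, str] | None:
        return self._gt.get((sample, normalize_chrom(chrom), pos))

    def has_site(self, chrom: str, pos: int) -> bool:
        return (normalize_chrom(chrom), pos) in self._sites

    def __len__(self) -> int:
        return len(self._gt)


def read_microarray(path: str | Path) -> MicroarrayGenotypes:
    """Read a chip-genotype TSV: chrom, pos, ref, alt, then one column
    per sample holding ``A/G``-style base pairs (``./.`` = missing)."""
    chip = MicroarrayGenotypes()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[4:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            chrom, pos = parts[0], int(parts[1])
            for sample, gt in zip(samples, parts[4:]):
                if gt in {"./.", ".", "", "--"}:
                    continue
                a1, _, a2 = gt.partition("/")
                chip.set(sample, chrom, pos, a1, a2)
    return chip


# ---------------------------------------------------------------------------
# VCF reading


class VcfReader:
    """Iterate a multi-sample VCF as :class:`VariantRecord` objects.

    Missing FORMAT subfields become MISSING (-1), never 0.  Multi-allelic
    sites yield one record.  Per-record field malformation skips the
    record and increments :attr:`n_skipped`.
    """

    def __init__(self, path: str | Path, region: str | None = None,
                 half_call_missing: bool = True) -> None:
        self.path = str(path)
        self.region = region
        #: policy for half-missing genotypes like ``./1``: treat the whole
        #: genotype as missing (default) or keep the called allele.
        self.half_call_missing = half_call_missing
        self._vcf = VCF(self.path, gts012=False)
        self.samples: list[str] = list(self._vcf.samples)
        self.n_skipped = 0

    def __iter__(self) -> Iterator[VariantRecord]:
        it = self._vcf
        want = None
        if self.region:
            indexed = any(Path(self.path + ext).exists() for ext in (".tbi", ".csi"))
            if indexed:  # indexed files support direct region queries
                it = self._vcf(self.region)
            else:  # plain text: full scan with a chrom filter
                want = normalize_chrom(self.region)
        for v in it:
            if want is not None and normalize_chrom(v.CHROM) != want:
                continue
            try:
                yield self._convert(v)
            except Exception:  # malformed record: skip, count
                self.n_skipped += 1
                logger.warning("skipped malformed record at %s:%s", v.CHROM, v.POS)

    def _convert(self, v) -> VariantRecord:
        n = len(self.samples)
        gts = np.full((n, 2), MISSING, dtype=np.int16)
        for i, g in enumerate(v.genotypes):
            alleles = g[:-1]
            if len(alleles) >= 2:
                a, b = alleles[0], alleles[1]
            elif len(alleles) == 1:  # haploid call: duplicate
                a = b = alleles[0]
            else:
                a = b = -1
            if self.half_call_missing and (a < 0 or b < 0):
                a = b = -1
            gts[i, 0], gts[i, 1] = max(a, -1), max(b, -1)

        ad = v.format("AD")
        if ad is not None:
            ad = ad.astype(np.int64)
            ad[ad < _INT_SENTINEL] = MISSING
            ad = np.where(ad < 0, MISSING, ad).astype(np.int32)

        dp = v.format("DP")
        if dp is not None:
            dp = dp.astype(np.int64)[:, 0]
            dp = np.where(dp < 0, MISSING, dp).astype(np.int32)
        else:
            dp = np.full(n, MISSING, dtype=np.int32)
        # fall back to the AD sum where DP itself is absent
        if ad is not None:
            ad_ok = (ad >= 0).all(axis=1)
            fallback = (dp == MISSING) & ad_ok
            if fallback.any():
                dp = dp.copy()
                dp[fallback] = ad[fallback].sum(axis=1)

        gq = v.format("GQ")
        if gq is not None:
            gq = np.asarray(gq).reshape(n, -1)[:, 0].astype(np.float64)
            gq = np.where(np.isnan(gq) | (gq < 0), MISSING, gq).astype(np.int32)
        else:
            gq = np.full(n, MISSING, dtype=np.int32)

        return VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=list(v.ALT or []),
            genotypes=gts,
            dp=dp,
            gq=gq,
            ad=ad,
            variant_id=None if v.ID in (None, ".") else v.ID,
        )


def read_vcf(path: str | Path, region: str | None = None,
             half_call_missing: bool = True) -> VcfReader:
    """Open a VCF for iteration; see :class:`VcfReader`."""
    return VcfReader(path, region=region, half_call_missing=half_call_missing)


# ---------------------------------------------------------------------------
# Output


def write_labels(path: str | Path, rows: Iterable[Mapping]) -> int:
    """Write the per-variant label TSV.

    Columns: chrom, pos, ref, alt, label (HIGH/LOW), stage
    (FILTER/PREDICTED), probability (empty for FILTER-stage calls), plus
    any extra keys present in the rows.  Returns the row count.
    """
    rows = list(rows)
    base = ["chrom", "pos", "ref", "alt", "label", "stage", "probability"]
    extra = [k for k in (rows[0].keys() if rows else []) if k not in base]
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(base + extra) + "\n")
        for r in rows:
            prob = r.get("probability")
            prob_s = "" if prob is None or (isinstance(prob, float) and np.isnan(prob)) else repr(float(prob))
            vals = [str(r["chrom"]), str(r["pos"]), r["ref"], r["alt"],
                    r["label"], r["stage"], prob_s]
            vals += ["" if r.get(k) is None else str(r.get(k)) for k in extra]
            fh.write("\t".join(vals) + "\n")
            n += 1
    return n


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def split_vcf(src: str | Path, labels: Sequence[str], high_path: str | Path,
              low_path: str | Path) -> tuple[int, int]:
    """Split a VCF into high- and low-quality files, byte-faithfully.

    ``labels`` holds "HIGH" or "LOW" per data line, in file order.  The
    original header and record lines are copied verbatim; only the
    routing differs.  Raises if the label count does not match the
    record count.
    """
    n_high = n_low = 0
    with _open_text(src) as fh, open(high_path, "w") as hi, open(low_path, "w") as lo:
        i = 0
        for line in fh:
            if line.startswith("#"):
                hi.write(line)
                lo.write(line)
                continue
            if i >= len(labels):
                raise ValueError("more VCF records than labels")
            if labels[i] == "HIGH":
                hi.write(line)
                n_high += 1
            else:
                lo.write(line)
                n_low += 1
            i += 1
    if i != len(labels):
        raise ValueError(f"label count {len(labels)} != record count {i}")
    return n_high, n_low
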