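"""Self-contained synthetic cohort generator.

Emulates the inputs of a family-based joint-genotyping study: a toy
reference chromosome with a GC gradient, trio-structured samples, a
multi-sample VCF with per-genotype GT/DP/GQ/AD, a dbSNP-style known-
sites list, a microarray extract, and a truth-label table.

Variants are planted in two classes.  "Good" variants have founder
genotypes drawn at Hardy-Weinberg equilibrium, clean Mendelian
transmission, balanced heterozygote read counts, high concentrated GQ
and DP, and (near-)zero missingness.  "Bad" variants receive Mendelian-
error injection in trios, random allele flips (which also break chip
concordance), skewed heterozygote allele balance, inflated missingness,
and low dispersed GQ/DP — the correlated signal profile of genuine
calling errors.  The microarray extract stores pre-error genotypes, so
chip discordance localises to corrupted variants.

Everything is deterministic given (config, seed): identical
configuration reproduces identical files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .qc_stats import genotype_consistent

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class ClassProfile:
    """Per-class distributions for one planted variant class.

    GQ/DP are per-sample normal draws (rounded, clipped); the
    heterozygote reference-read fraction is ``balance`` +- a uniform
    per-variant jitter; per-variant missingness is uniform on
    [missing_lo, missing_hi]; ``me_injection_rate`` is the per-trio
    probability of forcing a Mendelian-inconsistent child genotype;
    ``genotype_error_rate`` is the per-sample probability of flipping
    one allele (feeding chip discordance and secondary Mendel errors).
    """

    mean_gq: float
    sd_gq: float
    mean_dp: float
    sd_dp: float
    balance: float = 0.5
    balance_jitter: float = 0.0
    missing_lo: float = 0.0
    missing_hi: float = 0.0
    me_injection_rate: float = 0.0
    genotype_error_rate: float = 0.0


def good_profile() -> ClassProfile:
    """High-confidence calls: concentrated GQ~88, DP~35, balance 0.5."""
    return ClassProfile(mean_gq=88, sd_gq=6, mean_dp=35, sd_dp=6,
                        balance=0.5, balance_jitter=0.0,
                        missing_lo=0.0, missing_hi=0.005)


def bad_profile() -> ClassProfile:
    """Error-like calls: low dispersed GQ/DP, skewed balance, missingness,
    Mendelian-error injection at 0.3 per trio and 10% allele flips."""
    return ClassProfile(mean_gq=35, sd_gq=12, mean_dp=12, sd_dp=5,
                        balance=0.8, balance_jitter=0.1,
                        missing_lo=0.0, missing_hi=0.25,
                        me_injection_rate=0.3, genotype_error_rate=0.1)


@dataclass
class SimulationConfig:
    n_families: int = 30            # one trio per family
    trio_per_family: int = 1
    n_variants: int = 2000
    fraction_bad: float = 0.10
    fraction_indel: float = 0.05
    fraction_multiallelic: float = 0.02   # among SNVs
    fraction_known: float = 0.70
    chip_fraction: float = 0.30           # of common biallelic SNVs
    chrom: str = "1"
    chrom_length: int = 1_000_000
    window_size: int = 1000
    gc_range: tuple[float, float] = (0.30, 0.70)
    af_range: tuple[float, float] = (0.02, 0.50)
    good: ClassProfile = field(default_factory=good_profile)
    bad: ClassProfile = field(default_factory=bad_profile)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction_bad < 1.0):
            raise ValueError("fraction_bad must be in (0, 1)")
        if self.chrom_length < self.window_size:
            raise ValueError("chrom_length must be >= window_size")

    @property
    def well_separated(self) -> bool:
        """Whether the two class profiles are separable in GQ/DP."""
        return (self.good.mean_gq - self.bad.mean_gq
                > 2 * (self.good.sd_gq + self.bad.sd_gq))


@dataclass
class CohortPaths:
    fasta: Path
    vcf: Path
    ped: Path
    known: Path
    chip: Path
    truth: Path


def simulate_reference(cfg: SimulationConfig, path: str | Path) -> Path:
    """Write a random reference chromosome with a linear GC gradient
    across windows (so window GC content has dynamic range)."""
    rng = np.random.default_rng(cfg.seed)
    w = cfg.window_size
    n_win = (cfg.chrom_length + w - 1) // w
    gc_lo, gc_hi = cfg.gc_range
    targets = np.linspace(gc_lo, gc_hi, n_win)
    chunks = []
    for i in range(n_win):
        size = min(w, cfg.chrom_length - i * w)
        g = targets[i]
        p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T
        chunks.append(_BASES[rng.choice(4, size=size, p=p)])
    seq = np.concatenate(chunks).tobytes().decode("ascii")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")
    return path


def _sample_ids(cfg: SimulationConfig) -> tuple[list[str], list[tuple[str, str, str]]]:
    """(ordered sample ids, trios as (child, father, mother))."""
    samples: list[str] = []
    trios: list[tuple[str, str, str]] = []
    for f in range(cfg.n_families):
        fa, mo = f"fam{f}_fa", f"fam{f}_mo"
        samples += [fa, mo]
        for t in range(cfg.trio_per_family):
            ch = f"fam{f}_ch{t}"
            samples.append(ch)
            trios.append((ch, fa, mo))
    return samples, trios


def write_pedigree(cfg: SimulationConfig, path: str | Path) -> Path:
    samples, trios = _sample_ids(cfg)
    child_parents = {c: (f, m) for c, f, m in trios}
    path = Path(path)
    with open(path, "w") as fh:
        for s in samples:
            fam = s.split("_")[0]
            father, mother = child_parents.get(s, ("0", "0"))
            sex = "1" if s.endswith("_fa") else "2" if s.endswith("_mo") else \
                ("1" if int(s.rsplit("ch", 1)[-1]) % 2 == 0 else "2")
            fh.write(f"{fam}\t{s}\t{father}\t{mother}\t{sex}\t0\n")
    return path


_GT_CACHE: dict[int, list[tuple[int, int]]] = {}


def _all_genotypes(n_alleles: int) -> list[tuple[int, int]]:
    if n_alleles not in _GT_CACHE:
        _GT_CACHE[n_alleles] = [(a, b) for a in range(n_alleles)
                                for b in range(a, n_alleles)]
    return _GT_CACHE[n_alleles]


def _inconsistent_child_genotypes(father, mother, n_alleles):
    return [g for g in _all_genotypes(n_alleles)
            if not genotype_consistent(g, father, mother)]


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path) -> CohortPaths:
    """Generate the full fixture set under ``out_dir``.

    Writes reference FASTA, multi-sample VCF, PED, known-sites TSV,
    microarray TSV and a truth-label TSV; returns their paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = CohortPaths(
        fasta=out / "reference.fa", vcf=out / "cohort.vcf",
        ped=out / "cohort.ped", known=out / "known_sites.tsv",
        chip=out / "microarray.tsv", truth=out / "truth_labels.tsv",
    )
    simulate_reference(cfg, paths.fasta)
    with open(paths.fasta) as fh:
        seq = "".join(line.strip() for line in fh if not line.startswith(">"))

    write_pedigree(cfg, paths.ped)
    samples, trios = _sample_ids(cfg)
    n_samples = len(samples)
    sample_index = {s: i for i, s in enumerate(samples)}
    trio_idx = [(sample_index[c], sample_index[f], sample_index[m])
                for c, f, m in trios]
    founder_mask = np.array([s not in {t[0] for t in trios} for s in samples])

    rng = np.random.default_rng(cfg.seed + 1)

    n = cfg.n_variants
    positions = np.sort(rng.choice(cfg.chrom_length - 10, size=n, replace=False) + 1)
    is_bad = np.zeros(n, dtype=bool)
    is_bad[rng.choice(n, size=int(round(n * cfg.fraction_bad)), replace=False)] = True
    is_indel = np.zeros(n, dtype=bool)
    is_indel[rng.choice(n, size=int(round(n * cfg.fraction_indel)), replace=False)] = True
    snv_idx = np.flatnonzero(~is_indel)
    is_multi = np.zeros(n, dtype=bool)
    n_multi = int(round(len(snv_idx) * cfg.fraction_multiallelic))
    if n_multi:
        is_multi[rng.choice(snv_idx, size=n_multi, replace=False)] = True
    afs = rng.uniform(cfg.af_range[0], cfg.af_range[1], size=n)
    is_known = rng.random(n) < cfg.fraction_known

    vcf_lines: list[str] = []
    truth_rows: list[str] = []
    known_rows: list[str] = []
    chip_sites: list[tuple[str, int, str, str, np.ndarray]] = []

    for j in range(n):
        pos = int(positions[j])
        profile = cfg.bad if is_bad[j] else cfg.good
        ref_base = seq[pos - 1].upper()
        if ref_base not in "ACGT":  # defensive; generator only emits ACGT
            ref_base = "A"

        # alleles
        if is_indel[j]:
            if rng.random() < 0.5:  # insertion
                ins = "".join(chr(b) for b in _BASES[rng.integers(0, 4, size=rng.integers(1, 4))])
                ref, alts = ref_base, [ref_base + ins]
            else:  # deletion
                k = int(rng.integers(1, 4))
                ref, alts = seq[pos - 1: pos + k].upper(), [ref_base]
        elif is_multi[j]:
            ti = _TRANSITION[ref_base]
            others = [b for b in "ACGT" if b not in (ref_base, ti)]
            ref, alts = ref_base, [ti, others[int(rng.integers(0, 2))]]
        else:
            if rng.random() < 2 / 3:
                alt = _TRANSITION[ref_base]
            else:
                alt = [b for b in "ACGT" if b not in (ref_base, _TRANSITION[ref_base])][int(rng.integers(0, 2))]
            ref, alts = ref_base, [alt]
        n_alleles = 1 + len(alts)

        # founder genotypes at HWE given allele frequency
        af = afs[j]
        if n_alleles == 2:
            allele_p = np.array([1 - af, af])
        else:
            allele_p = np.array([1 - af, af * 0.7, af * 0.3])
        gt = np.zeros((n_samples, 2), dtype=np.int16)
        founder_rows = np.flatnonzero(founder_mask)
        gt[founder_rows] = rng.choice(n_alleles, size=(len(founder_rows), 2), p=allele_p)
        for ci, fi, mi in trio_idx:  # one allele from each parent
            gt[ci, 0] = gt[fi, int(rng.integers(0, 2))]
            gt[ci, 1] = gt[mi, int(rng.integers(0, 2))]

        truth_gt = gt.copy()  # pre-error state feeds the chip extract

        # corruption (bad class; rates are zero in the good profile)
        if profile.me_injection_rate > 0:
            for ci, fi, mi in trio_idx:
                if rng.random() >= profile.me_injection_rate:
                    continue
                father = (int(gt[fi, 0]), int(gt[fi, 1]))
                mother = (int(gt[mi, 0]), int(gt[mi, 1]))
                bad_gts = _inconsistent_child_genotypes(father, mother, n_alleles)
                if not bad_gts:  # het x het permits every child: force a hom parent
                    gt[fi] = (0, 0)
                    father = (0, 0)
                    bad_gts = _inconsistent_child_genotypes(father, mother, n_alleles)
                gt[ci] = bad_gts[int(rng.integers(0, len(bad_gts)))]
        if profile.genotype_error_rate > 0:
            flip = rng.random(n_samples) < profile.genotype_error_rate
            for si in np.flatnonzero(flip):
                which = int(rng.integers(0, 2))
                a = int(gt[si, which])
                gt[si, which] = (int(rng.integers(1, n_alleles)) if a == 0 else 0)

        # missingness
        miss_rate = rng.uniform(profile.missing_lo, profile.missing_hi)
        missing = rng.random(n_samples) < miss_rate

        # per-sample DP / GQ
        dp = np.maximum(1, np.rint(rng.normal(profile.mean_dp, profile.sd_dp,
                                              size=n_samples))).astype(int)
        gq = np.clip(np.rint(rng.normal(profile.mean_gq, profile.sd_gq,
                                        size=n_samples)), 0, 99).astype(int)

        # AD: binomial split of DP at the class balance for ref/alt hets
        balance = profile.balance + rng.uniform(-profile.balance_jitter,
                                                profile.balance_jitter)
        ad = np.zeros((n_samples, n_alleles), dtype=int)
        for si in range(n_samples):
            a, b = int(gt[si, 0]), int(gt[si, 1])
            d = int(dp[si])
            if a == b:
                ad[si, a] = d
            elif 0 in (a, b):
                alt_allele = a if a != 0 else b
                ref_reads = int(rng.binomial(d, min(max(balance, 0.0), 1.0)))
                ad[si, 0] = ref_reads
                ad[si, alt_allele] = d - ref_reads
            else:  # alt/alt het: even split
                r = int(rng.binomial(d, 0.5))
                ad[si, a] = r
                ad[si, b] = d - r

        # serialize the VCF data line
        fields = []
        for si in range(n_samples):
            if missing[si]:
                fields.append("./.:.:.:.")
            else:
                ad_s = ",".join(str(x) for x in ad[si])
                fields.append(f"{gt[si,0]}/{gt[si,1]}:{dp[si]}:{gq[si]}:{ad_s}")
        alt_s = ",".join(alts)
        vid = f"sim{j}" if is_known[j] else "."
        vcf_lines.append(
            f"{cfg.chrom}\t{pos}\t{vid}\t{ref}\t{alt_s}\t100\tPASS\t.\t"
            "GT:DP:GQ:AD\t" + "\t".join(fields))

        label = "bad" if is_bad[j] else "good"
        truth_rows.append(f"{cfg.chrom}\t{pos}\t{ref}\t{alt_s}\t{label}")
        if is_known[j]:
            for alt in alts:
                known_rows.append(f"{cfg.chrom}\t{pos}\tsim{j}\t{ref}\t{alt}")

        # chip extract: common biallelic SNVs, truth (pre-error) genotypes
        if (not is_indel[j] and not is_multi[j] and af >= 0.05
                and rng.random() < cfg.chip_fraction):
            chip_sites.append((cfg.chrom, pos, ref, alts[0], truth_gt))

    # ---- write outputs ---------------------------------------------------
    with open(paths.vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cfg.chrom},length={cfg.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        fh.write("\n".join(vcf_lines) + "\n")

    with open(paths.truth, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\n")
        fh.write("\n".join(truth_rows) + "\n")

    with open(paths.known, "w") as fh:
        fh.write("\n".join(known_rows) + ("\n" if known_rows else ""))

    with open(paths.chip, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, tgt in chip_sites:
            alleles = [ref, alt]
            cells = []
            for si in range(n_samples):
                a, b = int(tgt[si, 0]), int(tgt[si, 1])
                cells.append(f"{alleles[a]}/{alleles[b]}")
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t" + "\t".join(cells) + "\n")

    return paths


def read_truth_labels(path: str | Path) -> dict[tuple[str, int, str, str], str]:
    """truth TSV -> {(chrom, pos, ref, alt-string): 'good'|'bad'}."""
    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, pos, ref, alt, label = line.rstrip("\n").split("\t")
            out[(chrom, int(pos), ref, alt)] = label
    return out
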