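# Methods

## Model and procedure

`varforest` labels every site of a joint-genotyped multi-sample VCF as
high- or low-quality in two stages.

**Stage 1 — stringent two-sided filtering.**  Four statistics are
computed per site: genotype missing rate, Mendelian-error (ME) rate
over pedigree trios, the exact Hardy-Weinberg (HWE) test p-value, and
ABHet, the pooled reference-read fraction over ref/alt-heterozygous
samples.  Two threshold sets partition the call set: a variant is
high-quality when it satisfies *every* "good" bound, low-quality when
it violates *any* "bad" bound, and undetermined otherwise.  The
validator requires good bounds to be strictly stricter than bad
bounds, so the classes are disjoint by construction.

**Stage 2 — random-forest resolution.**  The filter-labelled variants
form the training set after class balancing (the majority class is
downsampled uniformly without replacement to the minority size, so the
balanced set is twice the minority count).  A forest of 50 trees is fit
on seven features — mean and population SD of per-sample DP, the same
for GQ, the outlier fractions of DP and GQ (samples strictly below the
dataset-wide first quartile, calibrated once on one chromosome), and
window GC content — and every undetermined variant receives the
fraction of trees voting high-quality as its probability.  Strictly
above 0.5 is called HIGH; ties and below go LOW.  Final high = filter
high ∪ predicted high, and the union of the final sets is exactly the
input.

SNVs (ref and all alts single bases) and indels run as two fully
separate streams: filters, calibration pooling aside, training and
prediction never mix them.  Mixed SNV/indel multi-allelic sites travel
with the indels (single conservative assignment).

### Assumptions

* Genotype errors leave correlated fingerprints: they violate trio
  transmission, skew heterozygote read balance, depress GQ/DP, and
  inflate missingness.  The filter stage needs only the clearest of
  these; the forest generalises the pattern to the ambiguous middle.
* The training labels produced by the filters are treated as ground
  truth; if the filters are badly mis-set the forest learns the wrong
  boundary.  The partition report therefore warns whenever the
  filter-stage low-quality fraction leaves the ~4–16% band that
  experience with large pedigree cohorts suggests.
* The exact HWE test assumes a homogeneous randomly mating sample; in
  strongly structured cohorts its p-values reject excessively, which is
  why the good-side threshold is a tunable.

## Statistic definitions and edge cases

* **Missing rate** counts missing *alleles* over 2N; a half-missing
  call such as `./1` is treated as fully missing by default (policy
  flag `half_call_missing`; the paper-style genotype-level reading is
  available by turning it off).
* **ME rate**: a trio is evaluable iff all three members are fully
  genotyped; the child is an error iff no assignment of one allele from
  each parent yields its genotype (brute-force enumeration verified:
  15 of the 27 ordered biallelic trio combinations are consistent).
  Computed on autosomes only — applying diploid trio logic to
  hemizygous calls would manufacture errors — so chrX/Y/MT return NA.
* **HWE p**: exact conditional test on the heterozygote count given
  allele counts, built by the standard ratio recurrence from the mode
  and normalised; the plain test, no mid-p correction.  Multi-allelic
  sites pool all alternate alleles into one class (the test is defined
  biallelically and this matches ABHet's ref-vs-nonref semantics).
  Validated against exact rational-arithmetic enumeration (≤ 1e-10 for
  all configurations with ≤ 20 samples; machine-precision in practice).
* **ABHet**: Σ AD_ref / Σ AD_total over included het samples — pooled,
  not averaged.  Ref/alt hets only; alt/alt hets (e.g. 1/2) have no
  reference reads to balance and are excluded.  On chrX only females
  are included when a pedigree is supplied.  NA when no qualifying het
  has usable AD.
* **NA semantics** in the filter stage: an NA statistic can neither
  trigger a bad bound nor satisfy a good one; a variant can still reach
  HIGH if its NA count is within `na_tolerance` (default 0).  When a
  resource is absent entirely (no pedigree → no ME), the statistic is
  dropped from both bound sets rather than tolerated.
* **DP** falls back to the AD sum when FORMAT/DP is absent; both absent
  → missing.  Missing is never coerced to zero.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| good: missing ≤ | 0.01 | fraction | stricter than the common 5% GWAS cut; the good set must be confident |
| good: ME ≤ | 0.01 | fraction | same reasoning |
| good: HWE p ≥ | 1e-2 | p-value | well above the common 1e-4 rejection threshold |
| good: ABHet ∈ | [0.45, 0.55] | fraction | tight band around the ideal 0.5 |
| bad: missing ≥ | 0.05 | fraction | the classical GWAS exclusion point |
| bad: ME ≥ | 0.05 | fraction | mirrors missing |
| bad: HWE p ≤ | 1e-6 | p-value | unambiguous equilibrium violation |
| bad: ABHet ∉ | [0.25, 0.75] | fraction | the classical allele-balance exclusion band |
| trees | 50 | count | accuracy/cost balance for forests at this feature count |
| probability threshold | 0.5 | fraction | majority vote; strict inequality, ties go LOW |
| GC window | 1000 | bp | matches the scale of local composition effects on coverage |
| calibration chromosome | "1" | — | one chromosome suffices for stable quartiles; a cost choice, CLI-overridable |
| rare/common MAF split | 0.03 | frequency | reporting convention |

These good/bad defaults are principled substitutes in the spirit of the
stringent-filtering design, not values validated on any real cohort;
they are meant to be tuned per study until the filter-stage low
fraction lands in the 4–16% band the partition report checks.

Tree hyperparameters beyond the count follow scikit-learn defaults and
are frozen into the serialized model (versioned joblib archive holding
parameters, feature order, imputation medians and the forest); loading
a model and predicting with mismatched feature order is a fatal error.

## Numerical choices

* First quartile: linear interpolation between order statistics
  (numpy's default), fixed so calibration is reproducible.
* SD: population convention (divide by n); the forest is insensitive to
  n vs n−1 but tests need one answer.
* Outlier comparison is strict `<`; equality to the quartile does not
  count as an outlier.
* Predict-time NA features are imputed with training-set medians and
  the affected rows are flagged (`imputed_mask`), so every undetermined
  variant receives a label and the partition property survives.
* Seeds: stream-level seeds are derived from the run seed via
  `numpy.random.SeedSequence`, keeping SNV and indel sampling
  independent yet reproducible; all outputs are byte-identical across
  reruns with the same inputs and seed.
* Degenerate streams: when the filter stage leaves fewer than two
  variants in either training class, the forest cannot be fit and the
  undetermined variants of that stream fall back to LOW with a warning
  (conservative: unresolvable evidence is not promoted).

## Synthetic data generator

The generator emulates a family-based sequencing study: a random
reference chromosome with a linear GC gradient (default 0.30 → 0.70
across 1-kb windows), trio families (default 30), and per-variant
founder genotypes drawn at HWE from a uniform allele-frequency spectrum
(0.02–0.5), transmitted one allele per parent.  Default mix: 10%
planted-bad variants, 5% indels, 2% multi-allelic SNVs, transition:
transversion drawn 2:1, 70% of sites listed as "known", a microarray
extract covering ~30% of common biallelic SNVs with pre-error
genotypes.

Class profiles: good variants have GQ ~ N(88, 6), DP ~ N(35, 6),
heterozygote balance 0.5, missingness ≤ 0.5%; bad variants have
GQ ~ N(35, 12), DP ~ N(12, 5), balance 0.8 ± 0.1, missingness uniform
up to 25%, per-trio Mendelian-error injection at rate 0.3 and a 10%
per-sample allele-flip rate.  Mendelian errors are injected by
replacing the child's genotype with one drawn uniformly from the
genotypes *inconsistent* with its parents (forcing a parent homozygous
first in the het×het case, where every child genotype is consistent);
this guarantees the planted per-trio error rate equals the injection
rate in expectation, which the generator self-consistency tests check.
Allele flips, applied to any sample, independently feed chip
discordance and secondary Mendel errors, and AD counts are binomial at
the class balance given the sample's DP, so the ABHet expectations are
analytic.

What the generator does **not** emulate: linkage disequilibrium and
regional error clustering, population structure and relatedness beyond
nuclear trios, coverage that tracks GC content (GC is informative in
real data precisely because coverage responds to it; here it is a pure
noise feature), strand bias, mapping artifacts around repeats, and
realistic allele-frequency spectra.  Passing the end-to-end recovery
tests therefore demonstrates that the machinery is correct and
well-calibrated under the stated error model — not that the default
thresholds transfer to any particular real cohort.

## Problem sizes used by the checks

The test suite exercises cohorts of 400–800 variants across 10–15 trio
families; the end-to-end recovery check and the acceptance script use
20,000 variants over 30 trio families (90 samples) on a 2-Mb reference,
which completes in well under a minute per run on a single CPU.  These
sizes give the binomial statistics enough resolution for the asserted
tolerances while keeping the default run cheap.

## Known limitations

* ME logic is diploid-autosomal only; sex chromosomes get NA rather
  than hemizygous trio rules.
* Chip comparison assumes matching strand and allele encoding;
  strand-flip resolution is out of scope (mismatched sites are skipped
  with a warning).
* The ABHet-only baseline classifier (`classify_abhet_baseline`,
  low iff ABHet > 0.7 or < 0.3) is included for comparison; it never
  abstains and treats NA as high, so it is a deliberately crude
  reference point.
* Multi-allelic sites are processed un-split; their HWE and ABHet use
  pooled-alt semantics, which blunts per-allele signal.
* The metrics report implements a deliberate core subset of variant-
  and sample-level quality metrics (those listed in `MetricsReport`);
  the report schema is a plain mapping and extensible.
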