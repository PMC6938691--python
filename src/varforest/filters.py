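"""Hard-filter stage: partition variants into HIGH / LOW / UNDETERMINED.

Two threshold sets drive the partition.  A variant is low-quality if it
violates ANY "bad" bound, high-quality if it satisfies ALL "good"
bounds, and undetermined otherwise; the undetermined set is what the
classifier later resolves.  Good bounds must be strictly stricter than
bad bounds on every shared statistic so the three classes are disjoint
by construction.

NA semantics: an NA statistic can neither trigger a bad bound nor
satisfy a good one; a variant may still be called HIGH if the number of
NA statistics among its good bounds is within ``na_tolerance``
(default 0).  When a resource is absent (no pedigree -> no Mendelian
error rate), drop that statistic from both bound sets instead of
raising the tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

logger = logging.getLogger(__name__)


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


class QcLabel(Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class Bound:
    """One per-statistic bound.

    kind "max": value must stay at or below the bound (missing rate, ME
    rate); "min": at or above (HWE p); "range": inside [lo, hi] (ABHet).
    For the bad set the same bound read in reverse defines violation:
    max -> x >= value, min -> x <= value, range -> x outside [lo, hi].
    Comparisons are inclusive on both sides; the config validator
    guarantees no value can satisfy a good bound and violate the
    corresponding bad bound at once.
    """

    kind: str  # "max" | "min" | "range"
    value: float = math.nan
    lo: float = math.nan
    hi: float = math.nan

    def good_ok(self, x: float) -> bool:
        if self.kind == "max":
            return x <= self.value
        if self.kind == "min":
            return x >= self.value
        return self.lo <= x <= self.hi

    def bad_violated(self, x: float) -> bool:
        if self.kind == "max":
            return x >= self.value
        if self.kind == "min":
            return x <= self.value
        return x < self.lo or x > self.hi


def _default_good() -> dict[str, Bound]:
    return {
        "missing_rate": Bound("max", 0.01),
        "mendel_error_rate": Bound("max", 0.01),
        "hwe_p": Bound("min", 1e-2),
        "abhet": Bound("range", lo=0.45, hi=0.55),
    }


def _default_bad() -> dict[str, Bound]:
    return {
        "missing_rate": Bound("max", 0.05),
        "mendel_error_rate": Bound("max", 0.05),
        "hwe_p": Bound("min", 1e-6),
        "abhet": Bound("range", lo=0.25, hi=0.75),
    }


@dataclass
class FilterConfig:
    """Good/bad threshold sets plus user-defined extra statistics.

    The defaults are deliberately stringent on the good side (the point
    of the filter stage is to hand the classifier confidently labelled
    training examples); they are meant to be tuned per study so the
    low-quality fraction after filtering lands in the recommended
    4-16% band (see :func:`partition_report`).
    """

    good: dict[str, Bound] = field(default_factory=_default_good)
    bad: dict[str, Bound] = field(default_factory=_default_bad)
    na_tolerance: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in set(self.good) & set(self.bad):
            g, b = self.good[name], self.bad[name]
            if g.kind != b.kind:
                raise ValueError(f"filter {name!r}: good/bad bound kinds differ")
            ok = (
                (g.kind == "max" and g.value < b.value)
                or (g.kind == "min" and g.value > b.value)
                or (g.kind == "range" and b.lo < g.lo and g.hi < b.hi)
            )
            if not ok:
                raise ValueError(
                    f"filter {name!r}: good bound must be strictly stricter "
                    f"than bad bound (good={g}, bad={b})")

    def without(self, *names: str) -> "FilterConfig":
        """A copy with the named statistics dropped from both sets
        (e.g. drop 'mendel_error_rate' when no pedigree is available)."""
        return FilterConfig(
            good={k: v for k, v in self.good.items() if k not in names},
            bad={k: v for k, v in self.bad.items() if k not in names},
            na_tolerance=self.na_tolerance,
        )


def classify_by_filters(stats: Mapping[str, float], cfg: FilterConfig) -> QcLabel:
    """LOW on any violated bad bound; HIGH when every non-NA good bound
    holds and the NA count is within tolerance; else UNDETERMINED."""
    for name, bound in cfg.bad.items():
        x = stats.get(name)
        if not _is_na(x) and bound.bad_violated(x):
            return QcLabel.LOW
    n_na = 0
    for name, bound in cfg.good.items():
        x = stats.get(name)
        if _is_na(x):
            n_na += 1
        elif not bound.good_ok(x):
            return QcLabel.UNDETERMINED
    if n_na <= cfg.na_tolerance:
        return QcLabel.HIGH
    return QcLabel.UNDETERMINED


def classify_abhet_baseline(abhet: float) -> QcLabel:
    """Allele-balance-only baseline: LOW iff ABHet > 0.7 or < 0.3, HIGH
    otherwise (including NA); never UNDETERMINED."""
    if _is_na(abhet):
        return QcLabel.HIGH
    return QcLabel.LOW if (abhet > 0.7 or abhet < 0.3) else QcLabel.HIGH


#: recommended post-filter low-quality fraction band
LOW_FRACTION_BAND = (0.04, 0.16)


@dataclass
class PartitionReport:
    n_high: int
    n_low: int
    n_undetermined: int
    warnings: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n_high + self.n_low + self.n_undetermined

    @property
    def low_fraction(self) -> float:
        return self.n_low / self.total if self.total else math.nan


def partition_report(labels) -> PartitionReport:
    """Count the filter-stage classes and warn when the low-quality
    fraction leaves the recommended ~4-16% calibration band."""
    counts = {QcLabel.HIGH: 0, QcLabel.LOW: 0, QcLabel.UNDETERMINED: 0}
    for lab in labels:
        counts[lab] += 1
    rep = PartitionReport(counts[QcLabel.HIGH], counts[QcLabel.LOW],
                          counts[QcLabel.UNDETERMINED])
    if rep.total and not (LOW_FRACTION_BAND[0] <= rep.low_fraction <= LOW_FRACTION_BAND[1]):
        msg = (f"low-quality fraction {rep.low_fraction:.3f} outside the "
               f"recommended {LOW_FRACTION_BAND[0]:.0%}-{LOW_FRACTION_BAND[1]:.0%} band; "
               "consider loosening or tightening the filter thresholds")
        rep.warnings.append(msg)
        logger.warning(msg)
    return rep
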