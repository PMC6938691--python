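"""Classifier features: depth/quality summaries, outlier ratios, GC content.

Seven features feed the random forest: mean and population SD of per-
sample DP, the same for GQ, the fraction of samples below the dataset-
wide first-quartile DP (resp. GQ), and the GC fraction of the fixed-size
reference window containing the variant.

The outlier thresholds are calibrated once per dataset from every
non-missing per-sample value on a single calibration chromosome
(default "1", configurable — restricting to one chromosome is a cost
choice, not a statistical one) using linear-interpolation quartiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from pyfaidx import Fasta

from .io import MISSING, VariantRecord, normalize_chrom

logger = logging.getLogger(__name__)

NA = math.nan

#: canonical feature order used by the classifier
FEATURE_NAMES = ["mean_dp", "sd_dp", "mean_gq", "sd_gq",
                 "outlier_dp", "outlier_gq", "gc"]


@dataclass(frozen=True)
class OutlierThresholds:
    """First-quartile DP and GQ cutoffs, calibrated on one chromosome."""

    dp_q1: float
    gq_q1: float
    source_chrom: str


def summarize_dp_gq(v: VariantRecord) -> tuple[float, float, float, float]:
    """(mean_dp, sd_dp, mean_gq, sd_gq) over non-missing per-sample values.

    SD is the population SD (divide by n); a single value has SD 0; a
    channel with no non-missing values yields an NA pair.
    """
    out = []
    for arr in (v.dp, v.gq):
        vals = arr[arr != MISSING]
        if len(vals) == 0:
            out += [NA, NA]
        else:
            out += [float(vals.mean()), float(vals.std())]
    return tuple(out)  # type: ignore[return-value]


def calibrate_outlier_thresholds(records: Iterable[VariantRecord],
                                 chrom: str = "1") -> OutlierThresholds:
    """Pool every non-missing per-sample DP and GQ on ``chrom``; return
    the lower quartile of each pool (linear interpolation)."""
    want = normalize_chrom(chrom)
    dp_pool: list[np.ndarray] = []
    gq_pool: list[np.ndarray] = []
    for v in records:
        if normalize_chrom(v.chrom) != want:
            continue
        dp_pool.append(v.dp[v.dp != MISSING])
        gq_pool.append(v.gq[v.gq != MISSING])
    dp_all = np.concatenate(dp_pool) if dp_pool else np.array([])
    gq_all = np.concatenate(gq_pool) if gq_pool else np.array([])
    if len(dp_all) == 0 and len(gq_all) == 0:
        raise ValueError(
            f"no variants with DP/GQ on calibration chromosome {chrom!r}; "
            "pass another chromosome")
    dp_q1 = float(np.quantile(dp_all, 0.25)) if len(dp_all) else 0.0
    gq_q1 = float(np.quantile(gq_all, 0.25)) if len(gq_all) else 0.0
    return OutlierThresholds(dp_q1=dp_q1, gq_q1=gq_q1, source_chrom=chrom)


def outlier_ratios(v: VariantRecord, thr: OutlierThresholds) -> tuple[float, float]:
    """Fractions of samples with DP (resp. GQ) strictly below threshold.

    The denominator is samples with a non-missing value in that channel;
    NA when it is empty.
    """
    out = []
    for arr, cut in ((v.dp, thr.dp_q1), (v.gq, thr.gq_q1)):
        vals = arr[arr != MISSING]
        out.append(float((vals < cut).mean()) if len(vals) else NA)
    return tuple(out)  # type: ignore[return-value]


class GCWindowIndex:
    """Per-chromosome GC fraction of consecutive fixed-size windows.

    Windows tile each chromosome from its first base; the last window
    may be short.  Bases outside {A, C, G, T} (any case) are excluded
    from numerator and denominator; a window with no informative base
    is NA.
    """

    def __init__(self, window_size: int = 1000) -> None:
        if window_size < 1:
            raise ValueError("window_size must be >= 1")
        self.window_size = window_size
        self._gc: dict[str, np.ndarray] = {}
        self._warned: set[str] = set()

    def add_sequence(self, chrom: str, seq: str) -> None:
        w = self.window_size
        b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_gc = (b == ord("G")) | (b == ord("C"))
        is_at = (b == ord("A")) | (b == ord("T"))
        n_win = (len(b) + w - 1) // w
        pad = n_win * w - len(b)
        if pad:
            is_gc = np.pad(is_gc, (0, pad))
            is_at = np.pad(is_at, (0, pad))
        gc = is_gc.reshape(n_win, w).sum(axis=1).astype(float)
        informative = gc + is_at.reshape(n_win, w).sum(axis=1)
        with np.errstate(invalid="ignore"):
            frac = np.where(informative > 0, gc / np.maximum(informative, 1), NA)
        frac[informative == 0] = NA
        self._gc[normalize_chrom(chrom)] = frac

    def chromosomes(self) -> list[str]:
        return list(self._gc)

    def windows(self, chrom: str) -> np.ndarray:
        return self._gc[normalize_chrom(chrom)]

    def gc_at(self, chrom: str, pos: int) -> float:
        """GC fraction of the window containing 1-based ``pos``; NA if the
        contig is absent from the reference."""
        arr = self._gc.get(normalize_chrom(chrom))
        if arr is None:
            if chrom not in self._warned:
                self._warned.add(chrom)
                logger.warning("contig %r absent from reference; GC set to NA", chrom)
            return NA
        idx = (pos - 1) // self.window_size
        if idx >= len(arr):
            return NA
        return float(arr[idx])


def build_gc_index(fasta: str | Path, window_size: int = 1000) -> GCWindowIndex:
    """Index GC content of an (indexed) FASTA in fixed windows."""
    idx = GCWindowIndex(window_size=window_size)
    ref = Fasta(str(fasta))
    for name in ref.keys():
        idx.add_sequence(name, str(ref[name][:]))
    return idx


def gc_of_variant(v: VariantRecord, idx: GCWindowIndex) -> float:
    return idx.gc_at(v.chrom, v.pos)


def compute_features(v: VariantRecord, thr: OutlierThresholds,
                     idx: GCWindowIndex | None) -> dict[str, float]:
    """The seven classifier features for one variant, in canonical order."""
    mean_dp, sd_dp, mean_gq, sd_gq = summarize_dp_gq(v)
    out_dp, out_gq = outlier_ratios(v, thr)
    gc = gc_of_variant(v, idx) if idx is not None else NA
    return {"mean_dp": mean_dp, "sd_dp": sd_dp, "mean_gq": mean_gq,
            "sd_gq": sd_gq, "outlier_dp": out_dp, "outlier_gq": out_gq,
            "gc": gc}
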