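"""End-to-end orchestration: stats -> filter -> train -> predict -> merge -> evaluate.

SNVs and indels run as two fully separate streams (filtered, trained
and predicted independently); a site is an SNV iff ref and every alt
are single bases, so mixed multi-allelic sites travel with the indels.

Outputs per run: a per-variant label TSV (with stage, probability and
all statistics), byte-faithful high/low VCF splits, a metrics report
for the final high-quality set of each stream, and a JSON manifest
whose counts satisfy the conservation identities.  With a fixed seed
the whole run is deterministic: label files and manifests reproduce
byte for byte.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import build_training_set, merge_final_sets, train
from .config import RunConfig
from .evaluation import summarize
from .features import (FEATURE_NAMES, OutlierThresholds, build_gc_index,
                       calibrate_outlier_thresholds, compute_features)
from .filters import QcLabel, classify_by_filters, partition_report
from .io import (Pedigree, VariantRecord, read_pedigree, read_vcf,
                 split_vcf, write_labels)
from .qc_stats import compute_filter_stats

logger = logging.getLogger(__name__)

STAT_NAMES = ["missing_rate", "mendel_error_rate", "hwe_p", "abhet", "maf"]


@dataclass
class RunManifest:
    inputs: dict = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0
    version: str = __version__
    streams: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def stats_table(records: list[VariantRecord], samples: list[str],
                ped: Pedigree | None, thresholds: OutlierThresholds,
                gc_index) -> pd.DataFrame:
    """Per-variant table of the filter statistics and the seven features."""
    sample_index = {s: i for i, s in enumerate(samples)}
    rows = []
    for v in records:
        s = compute_filter_stats(v, ped, sample_index)
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
            "alt": ",".join(v.alts),
            "variant_type": "snv" if v.is_snv else "indel",
            "missing_rate": s.missing_rate,
            "mendel_error_rate": s.mendel_error_rate,
            "hwe_p": s.hwe_p, "abhet": s.abhet, "maf": s.maf,
        }
        row.update(compute_features(v, thresholds, gc_index))
        rows.append(row)
    return pd.DataFrame(rows)


def classify_stats_frame(stats: pd.DataFrame, filters) -> list[QcLabel]:
    return [classify_by_filters(row, filters)
            for row in stats.to_dict(orient="records")]


def _derive_seed(seed: int, stream: str) -> int:
    ss = np.random.SeedSequence([seed, {"snv": 1, "indel": 2}[stream]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class StreamResult:
    stats: pd.DataFrame
    filter_labels: list[QcLabel]
    final_labels: list[str]            # "HIGH"/"LOW" per variant, in order
    probabilities: list[float | None]  # None for FILTER-stage calls
    stages: list[str]                  # FILTER / PREDICTED
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def process_stream(stats: pd.DataFrame, cfg: RunConfig, seed: int,
                   stream: str) -> StreamResult:
    """Filter, train, predict and merge one variant stream."""
    filters = cfg.filters
    if stats["mendel_error_rate"].isna().all():
        filters = filters.without("mendel_error_rate")
    labels = classify_stats_frame(stats, filters)
    report = partition_report(labels)
    counts = {
        "input": len(stats),
        "filter_high": report.n_high,
        "filter_low": report.n_low,
        "undetermined": report.n_undetermined,
    }
    warnings_ = list(report.warnings)
    if report.total == 0:
        raise RuntimeError(f"{stream}: no variants to process")

    lab_arr = np.array([l.value for l in labels])
    undet = np.flatnonzero(lab_arr == "UNDETERMINED")
    features = stats[FEATURE_NAMES]

    pred_prob = np.full(len(stats), np.nan)
    pred_label = dict.fromkeys(undet.tolist())
    if len(undet) and report.n_high >= 2 and report.n_low >= 2:
        mask = lab_arr != "UNDETERMINED"
        ts = build_training_set(features[mask], lab_arr[mask],
                                seed=_derive_seed(seed, stream))
        model = train(ts, n_trees=cfg.n_trees,
                      probability_threshold=cfg.probability_threshold)
        p, plabels = model.predict_labels(features.iloc[undet])
        pred_prob[undet] = p
        pred_label = dict(zip(undet.tolist(), plabels))
        counts["predicted_high"] = sum(1 for l in plabels if l is QcLabel.HIGH)
        counts["predicted_low"] = len(plabels) - counts["predicted_high"]
    elif len(undet):
        # degenerate: a near-empty training class leaves nothing to learn
        # from; undetermined variants fall back to LOW (conservative)
        msg = (f"{stream}: filter stage yielded a class too small to train "
               f"(high={report.n_high}, low={report.n_low}); "
               "undetermined variants kept LOW")
        warnings_.append(msg)
        logger.warning(msg)
        pred_label = {int(i): QcLabel.LOW for i in undet}
        counts["predicted_high"] = 0
        counts["predicted_low"] = len(undet)
    else:
        counts["predicted_high"] = counts["predicted_low"] = 0

    fh = set(np.flatnonzero(lab_arr == "HIGH").tolist())
    fl = set(np.flatnonzero(lab_arr == "LOW").tolist())
    final_high, final_low = merge_final_sets(fh, fl, pred_label)
    assert len(final_high) + len(final_low) == len(stats)
    counts["final_high"] = len(final_high)
    counts["final_low"] = len(final_low)

    final_labels, stages, probs = [], [], []
    for i in range(len(stats)):
        final_labels.append("HIGH" if i in final_high else "LOW")
        if i in pred_label:
            stages.append("PREDICTED")
            probs.append(float(pred_prob[i]) if not math.isnan(pred_prob[i]) else None)
        else:
            stages.append("FILTER")
            probs.append(None)
    return StreamResult(stats=stats, filter_labels=labels,
                        final_labels=final_labels, probabilities=probs,
                        stages=stages, counts=counts, warnings=warnings_)


def run(vcf: str | Path, fasta: str | Path, out_dir: str | Path, seed: int,
        ped: str | Path | None = None, known: str | Path | None = None,
        chip: str | Path | None = None, cfg: RunConfig | None = None,
        ) -> RunManifest:
    """Execute the full QC pipeline; see the module docstring."""
    from .io import read_known_sites, read_microarray

    cfg = cfg or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pedigree = read_pedigree(ped) if ped else None
    known_sites = read_known_sites(known) if known else None
    chip_data = read_microarray(chip) if chip else None

    reader = read_vcf(vcf, half_call_missing=cfg.half_call_missing)
    samples = reader.samples
    records = list(reader)
    if not records:
        raise RuntimeError("input VCF holds no records")

    gc_index = build_gc_index(fasta, window_size=cfg.window_size)
    thresholds = calibrate_outlier_thresholds(records, chrom=cfg.calib_chrom)

    manifest = RunManifest(
        inputs={"vcf": str(vcf), "fasta": str(fasta),
                "ped": str(ped) if ped else None,
                "known": str(known) if known else None,
                "chip": str(chip) if chip else None},
        config_hash=cfg.digest(), seed=seed,
    )
    if pedigree is None:
        manifest.warnings.append("ME: disabled (no pedigree supplied)")

    stream_of = ["snv" if v.is_snv else "indel" for v in records]
    all_final: list[str | None] = [None] * len(records)

    for stream in ("snv", "indel"):
        idx = [i for i, s in enumerate(stream_of) if s == stream]
        if not idx:
            continue
        recs = [records[i] for i in idx]
        stats = stats_table(recs, samples, pedigree, thresholds, gc_index)
        result = process_stream(stats, cfg, seed, stream)
        manifest.streams[stream] = result.counts
        manifest.warnings.extend(result.warnings)

        rows = []
        for k, i in enumerate(idx):
            all_final[i] = result.final_labels[k]
            row = {
                "chrom": recs[k].chrom, "pos": recs[k].pos,
                "ref": recs[k].ref, "alt": ",".join(recs[k].alts),
                "label": result.final_labels[k],
                "stage": result.stages[k],
                "probability": result.probabilities[k],
            }
            for col in STAT_NAMES + FEATURE_NAMES:
                val = result.stats.iloc[k][col]
                row[col] = "" if pd.isna(val) else repr(float(val))
            rows.append(row)
        write_labels(out / f"labels_{stream}.tsv", rows)

        report = summarize([recs[k] for k in range(len(recs))
                            if result.final_labels[k] == "HIGH"],
                           samples, ped=pedigree, chip=chip_data,
                           known=known_sites)
        with open(out / f"metrics_{stream}.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    assert all(l in ("HIGH", "LOW") for l in all_final)
    n_high, n_low = split_vcf(vcf, all_final, out / "high_quality.vcf",
                              out / "low_quality.vcf")
    manifest.streams["total"] = {
        "input": len(records), "final_high": n_high, "final_low": n_low}
    manifest.write(out / "manifest.json")
    return manifest
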