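"""YAML run configuration.

Layout::

    filters:
      good: {missing_rate: 0.01, mendel_error_rate: 0.01,
             hwe_p: 1.0e-2, abhet: [0.45, 0.55]}
      bad:  {missing_rate: 0.05, mendel_error_rate: 0.05,
             hwe_p: 1.0e-6, abhet: [0.25, 0.75]}
      na_tolerance: 0
    model:
      trees: 50
      probability_threshold: 0.5
    features:
      window_size: 1000
      calib_chrom: "1"

Scalar bounds are read with the statistic's natural direction
(missing/Mendel rates are upper bounds, the HWE p-value a lower bound);
two-element lists are inclusive ranges.  Unknown statistic names are
accepted as user-defined filters and matched against identically named
columns of the per-variant stats table; scalars there are upper bounds
unless written as ``{min: x}`` / ``{max: x}`` / ``[lo, hi]``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .filters import Bound, FilterConfig

#: natural bound direction for the built-in statistics
_KIND = {"missing_rate": "max", "mendel_error_rate": "max",
         "hwe_p": "min", "abhet": "range"}


def _parse_bound(name: str, value) -> Bound:
    if isinstance(value, (list, tuple)):
        if len(value) != 2:
            raise ValueError(f"filter {name!r}: range needs [lo, hi]")
        return Bound("range", lo=float(value[0]), hi=float(value[1]))
    if isinstance(value, dict):
        if "min" in value:
            return Bound("min", float(value["min"]))
        if "max" in value:
            return Bound("max", float(value["max"]))
        raise ValueError(f"filter {name!r}: dict bound needs 'min' or 'max'")
    return Bound(_KIND.get(name, "max"), float(value))


@dataclass
class RunConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    n_trees: int = 50
    probability_threshold: float = 0.5
    window_size: int = 1000
    calib_chrom: str = "1"
    half_call_missing: bool = True

    def digest(self) -> str:
        """Stable hash of the effective configuration."""
        blob = {
            "good": {k: vars(b) for k, b in sorted(self.filters.good.items())},
            "bad": {k: vars(b) for k, b in sorted(self.filters.bad.items())},
            "na_tolerance": self.filters.na_tolerance,
            "n_trees": self.n_trees,
            "probability_threshold": self.probability_threshold,
            "window_size": self.window_size,
            "calib_chrom": self.calib_chrom,
            "half_call_missing": self.half_call_missing,
        }
        return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; every omitted key keeps its default."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    filt = raw.get("filters", {})
    good = dict(cfg.filters.good)
    bad = dict(cfg.filters.bad)
    if "good" in filt:
        good = {k: _parse_bound(k, v) for k, v in filt["good"].items()}
    if "bad" in filt:
        bad = {k: _parse_bound(k, v) for k, v in filt["bad"].items()}
    cfg.filters = FilterConfig(good=good, bad=bad,
                               na_tolerance=int(filt.get("na_tolerance", 0)))
    model = raw.get("model", {})
    cfg.n_trees = int(model.get("trees", cfg.n_trees))
    cfg.probability_threshold = float(model.get("probability_threshold",
                                                cfg.probability_threshold))
    feats = raw.get("features", {})
    cfg.window_size = int(feats.get("window_size", cfg.window_size))
    cfg.calib_chrom = str(feats.get("calib_chrom", cfg.calib_chrom))
    io = raw.get("io", {})
    cfg.half_call_missing = bool(io.get("half_call_missing", cfg.half_call_missing))
    return cfg
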