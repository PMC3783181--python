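"""Genome-average threshold and per-gene profile features.

Four features summarize a smoothed profile against a genome-wide
threshold capturing the average codon speed under the reference
condition:

(i)   average time — arithmetic mean of the smoothed times;
(ii)  slowest point — the longest translation time in the smoothed profile;
(iii) drop count — number of maximal contiguous regions slower than the
      threshold (1 when the entire profile is below);
(iv)  maximal drop length — width in codons of the longest such region
      (undefined, and the gene excluded from this feature, when the
      whole profile lies below).

A single threshold per data set makes conditions comparable; a
per-condition mode (threshold recomputed from each condition's own
profiles) shows how profile *shapes* vary once the overall speed shift
is discounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import SpeedProfile

__all__ = [
    "ThresholdValue",
    "FeatureSet",
    "genome_threshold",
    "compute_features",
    "feature_distributions",
    "write_features_tsv",
]


@dataclass(frozen=True)
class ThresholdValue:
    """Genome-average profile value on either the time or the speed scale."""

    value: float
    scale: str  # "time" | "speed"
    source_condition: str

    def __post_init__(self) -> None:
        if self.scale not in ("time", "speed"):
            raise ValueError(f"scale must be 'time' or 'speed', got {self.scale!r}")
        if not self.value > 0:
            raise ValueError(f"threshold must be positive, got {self.value}")


@dataclass(frozen=True)
class FeatureSet:
    """The four per-gene profile features relative to a threshold.

    ``max_drop_length`` is ``None`` (and ``excluded`` True) when the
    profile lies entirely below the threshold.
    """

    gene_id: str
    condition: str
    average_time: float
    slowest_point: float
    drop_count: int
    max_drop_length: Optional[int]
    excluded: bool = False


def genome_threshold(
    profiles: Iterable[SpeedProfile], scale: str = "speed"
) -> ThresholdValue:
    """Mean over the concatenated smoothed positions of all profiles.

    Length-weighted: every smoothed position counts once, so long genes
    contribute proportionally to their length.  On the speed scale the
    per-position values are the reciprocal smoothed times.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot compute a threshold from an empty profile set")
    conditions = {p.condition for p in profiles}
    if len(conditions) != 1:
        raise ValueError(f"profiles span multiple conditions: {sorted(conditions)}")
    values = np.concatenate([p.smoothed_times for p in profiles])
    if scale == "speed":
        values = 1.0 / values
    return ThresholdValue(
        value=float(values.mean()), scale=scale, source_condition=conditions.pop()
    )


def _run_lengths(below: np.ndarray) -> List[int]:
    """Lengths of maximal True runs."""
    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return (ends - starts).tolist()


def compute_features(p: SpeedProfile, threshold: ThresholdValue) -> FeatureSet:
    """Evaluate the four features of one profile against a threshold.

    "Below threshold" means slower than the genome average, with strict
    inequality: on the speed scale ``speed < threshold``, on the time
    scale ``time > threshold``.  Positions exactly at the threshold do
    not count as below.
    """
    smoothed = p.smoothed_times
    if threshold.scale == "speed":
        below = p.speed < threshold.value
    else:
        below = smoothed > threshold.value
    if below.all():
        drop_count, max_drop, excluded = 1, None, True
    else:
        runs = _run_lengths(below)
        drop_count = len(runs)
        max_drop = max(runs) if runs else 0
        excluded = False
    return FeatureSet(
        gene_id=p.gene_id,
        condition=p.condition,
        average_time=float(smoothed.mean()),
        slowest_point=float(smoothed.max()),
        drop_count=drop_count,
        max_drop_length=max_drop,
        excluded=excluded,
    )


_FEATURE_NAMES = ("average_time", "slowest_point", "drop_count", "max_drop_length")


def feature_distributions(
    features: Sequence[FeatureSet], bins: int = 30
) -> Dict[str, dict]:
    """Histogram and median per feature.

    Genes flagged ``excluded`` are left out of the maximal-drop-length
    distribution only.  Returns
    ``{feature: {"median", "counts", "bin_edges", "n"}}``.
    """
    if not features:
        raise ValueError("empty feature list")
    out: Dict[str, dict] = {}
    for name in _FEATURE_NAMES:
        if name == "max_drop_length":
            values = np.array(
                [f.max_drop_length for f in features if not f.excluded], dtype=float
            )
        else:
            values = np.array([getattr(f, name) for f in features], dtype=float)
        if values.size == 0:
            out[name] = {"median": math.nan, "counts": np.array([]), "bin_edges": np.array([]), "n": 0}
            continue
        counts, edges = np.histogram(values, bins=bins)
        out[name] = {
            "median": float(np.median(values)),
            "counts": counts,
            "bin_edges": edges,
            "n": int(values.size),
        }
    return out


def write_features_tsv(features: Iterable[FeatureSet], path) -> None:
    rows = [
        {
            "gene": f.gene_id,
            "condition": f.condition,
            "average_time": f.average_time,
            "slowest_point": f.slowest_point,
            "drop_count": f.drop_count,
            "max_drop_length": "" if f.max_drop_length is None else f.max_drop_length,
            "excluded_from_max_drop": f.excluded,
        }
        for f in features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
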