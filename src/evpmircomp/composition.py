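"""Background detection calls and per-sample composition statistics.

A probe is "detected" in a sample when its normalized count strictly
exceeds that sample's background threshold, defined as the mean plus 1.5
sample standard deviations (n-1 denominator) of the sample's negative
controls.  Three per-sample summaries follow:

* ``total_counts_log2`` -- log2 of the sum of normalized counts over every
  endogenous probe, detected or not (totals are right-skewed, hence the
  log);
* ``richness`` (s) -- the number of distinct probes detected;
* ``evenness`` -- the Pielou statistic -sum(p_i ln p_i) / ln s over the
  detected probes with p_i the within-sample relative proportion; bounded
  in [0, 1], equal to 1 when all detected probes are equally abundant, and
  undefined (missing) when s <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, EvpMirCompError
from .nanostring_io import NormalizedCounts

DEFAULT_SD_MULTIPLIER = 1.5


@dataclass
class DetectionMatrix:
    """Boolean detected matrix (endogenous probes x samples) + thresholds."""

    detected: pd.DataFrame
    thresholds: pd.Series
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER
    dialect: str = "normalized"

    @property
    def detection_rates(self) -> pd.Series:
        """Per-probe fraction of samples in which the probe is detected."""
        return self.detected.mean(axis=1)


def detection_threshold(
    neg_counts: np.ndarray | pd.Series, sd_multiplier: float = DEFAULT_SD_MULTIPLIER
) -> float:
    """Background threshold: mean + ``sd_multiplier`` * SD of the negatives.

    The SD uses the n-1 denominator; at least two negative-control values
    are required for it to be defined.
    """
    x = np.asarray(neg_counts, dtype=float)
    if x.size < 2:
        raise DegenerateInputError(
            "need >= 2 negative-control values for a detection threshold"
        )
    return float(x.mean() + sd_multiplier * x.std(ddof=1))


def call_detection(
    norm: NormalizedCounts,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    dialect: str = "normalized",
) -> DetectionMatrix:
    """Detection calls for every endogenous probe in every sample.

    ``dialect`` controls the scale on which negatives define the
    threshold: ``"normalized"`` (default) multiplies negative controls by
    the sample's normalization factor so the comparison with normalized
    endogenous counts is scale-consistent; ``"raw"`` thresholds the raw
    negatives and compares against counts de-scaled back to the raw scale
    (equivalently: raw counts vs raw-negative threshold).
    """
    if dialect not in ("normalized", "raw"):
        raise EvpMirCompError(f"unknown detection dialect {dialect!r}")
    if dialect == "normalized":
        negatives = norm.negatives
        compare = norm.counts
    else:
        negatives = norm.raw_negatives
        compare = norm.counts.div(norm.norm_factors, axis=1)
    if negatives is None:
        raise EvpMirCompError(
            "normalized counts carry no negative controls; detection threshold "
            "would be on a different scale than the compared values"
        )
    thresholds = pd.Series(
        {s: detection_threshold(negatives[s], sd_multiplier) for s in compare.columns},
        name="threshold",
    )
    detected = compare.gt(thresholds, axis=1)
    return DetectionMatrix(
        detected=detected,
        thresholds=thresholds,
        sd_multiplier=sd_multiplier,
        dialect=dialect,
    )


def total_counts_log2(norm: NormalizedCounts) -> pd.Series:
    """log2 per-sample sum of normalized counts over all endogenous probes."""
    totals = norm.counts.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        raise EvpMirCompError(
            f"zero total counts in samples {totals.index[zero].tolist()}"
        )
    return np.log2(totals).rename("total_counts_log2")


def richness(det: DetectionMatrix) -> pd.Series:
    """Number of detected probes per sample (column sums)."""
    return det.detected.sum(axis=0).rename("richness")


def evenness(norm: NormalizedCounts, det: DetectionMatrix) -> pd.Series:
    """Pielou evenness over detected probes; NaN when fewer than 2 detected."""
    out = pd.Series(np.nan, index=norm.counts.columns, dtype=float, name="evenness")
    for s in norm.counts.columns:
        mask = det.detected[s].to_numpy()
        vals = norm.counts[s].to_numpy()[mask]
        if vals.size <= 1:
            continue
        if (vals <= 0).any():
            raise EvpMirCompError(
                f"sample {s}: detected probe with non-positive normalized count"
            )
        p = vals / vals.sum()
        shannon = float(-(p * np.log(p)).sum())
        out[s] = shannon / np.log(vals.size)
    return out


def summarize_composition(
    norm: NormalizedCounts,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    dialect: str = "normalized",
) -> tuple[pd.DataFrame, DetectionMatrix]:
    """Full per-sample composition table + the detection matrix behind it.

    Columns: ``total_counts_log2, richness, evenness, threshold``.
    """
    det = call_detection(norm, sd_multiplier=sd_multiplier, dialect=dialect)
    table = pd.concat(
        [total_counts_log2(norm), richness(det), evenness(norm, det), det.thresholds],
        axis=1,
    )
    table.index.name = "sample_id"
    return table, det
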