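"""Reading, writing and normalizing NanoString nCounter-style count data.

The central container is :class:`RawCounts`: a probes x samples integer
matrix plus a per-probe class label (``endogenous``, ``positive``,
``negative``, ``spikein``, ``housekeeping``).  Counts are normalized to the
sample-specific positive controls: each lane is rescaled so that the
geometric mean of its positive-control probes matches the cohort average
(the standard CodeCount correction).  Normalization is a per-sample scalar,
so within-sample probe ratios and rank order are untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    LinkageError,
    NormalizationError,
)

PROBE_CLASSES = ("endogenous", "positive", "negative", "spikein", "housekeeping")

#: CodeClass names used in RCC lane files, mapped onto our probe classes.
RCC_CODECLASS_MAP = {
    "Endogenous": "endogenous",
    "Endogenous1": "endogenous",
    "Positive": "positive",
    "Negative": "negative",
    "SpikeIn": "spikein",
    "Housekeeping": "housekeeping",
}
_RCC_CLASS_INV = {
    "endogenous": "Endogenous",
    "positive": "Positive",
    "negative": "Negative",
    "spikein": "SpikeIn",
    "housekeeping": "Housekeeping",
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class RawCounts:
    """Integer count matrix (probes x samples) with probe-class labels.

    Parameters
    ----------
    counts
        DataFrame indexed by probe id with one column per sample id.
    probe_class
        Series indexed like ``counts`` with values drawn from
        :data:`PROBE_CLASSES`.
    """

    counts: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if not self.counts.index.equals(self.probe_class.index):
            self.probe_class = self.probe_class.reindex(self.counts.index)
        if self.probe_class.isna().any():
            missing = self.probe_class.index[self.probe_class.isna()].tolist()
            raise FormatError(f"probes without a class label: {missing}")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise FormatError(f"unknown probe classes: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")

    # -- convenience views ------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.counts.loc[self.probe_class == cls]

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.of_class("endogenous")

    @property
    def positive(self) -> pd.DataFrame:
        return self.of_class("positive")

    @property
    def negative(self) -> pd.DataFrame:
        return self.of_class("negative")


@dataclass
class NormalizedCounts:
    """Positive-control normalized endogenous counts.

    ``counts`` holds real-valued normalized counts for the endogenous probes
    only; ``norm_factors`` is the per-sample scalar that was applied.
    ``negatives`` carries the negative-control counts on the same scale
    (raw counts times the sample factor) so that detection thresholds can be
    computed scale-consistently downstream.
    """

    counts: pd.DataFrame
    norm_factors: pd.Series
    negatives: pd.DataFrame | None = None
    raw_negatives: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class QCReport:
    """Spike-in QC flags and positive-control linearity per sample."""

    spikein_counts: pd.Series
    flags: pd.Series  # "pass" | "warn"
    positive_linearity: pd.Series  # Pearson r of log counts vs log titration

    def to_dict(self) -> dict:
        return {
            "spikein_counts": self.spikein_counts.to_dict(),
            "flags": self.flags.to_dict(),
            "positive_linearity": {
                k: (None if pd.isna(v) else float(v))
                for k, v in self.positive_linearity.items()
            },
        }


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------

CovariateKind = Literal["continuous", "binary", "categorical"]


@dataclass
class CovariateSchema:
    """Declared type for one covariate column.

    ``levels`` orders categories; the first level is the reference in models.
    """

    name: str
    kind: CovariateKind
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind in ("binary", "categorical") and not self.levels:
            raise ConfigurationError(
                f"covariate {self.name!r}: {self.kind} covariates need declared levels"
            )
        if self.kind == "binary" and self.levels is not None and len(self.levels) != 2:
            raise ConfigurationError(
                f"covariate {self.name!r}: binary covariates need exactly 2 levels"
            )


@dataclass
class SampleAnnotations:
    """Typed covariate table, one row per sample."""

    data: pd.DataFrame  # indexed by sample_id
    schema: dict[str, CovariateSchema] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in annotations")
        for name, sch in self.schema.items():
            if name not in self.data.columns:
                raise FormatError(f"schema covariate {name!r} missing from table")
            col = self.data[name]
            if sch.kind == "continuous":
                self.data[name] = pd.to_numeric(col, errors="raise")
            else:
                vals = set(col.dropna().astype(str).unique())
                unknown = vals - set(sch.levels or ())
                if unknown:
                    raise FormatError(
                        f"covariate {name!r}: unknown categories {sorted(unknown)}"
                    )
                self.data[name] = pd.Categorical(
                    col.astype(object).where(col.notna(), np.nan),
                    categories=list(sch.levels or ()),
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def kind_of(self, covariate: str) -> CovariateKind:
        if covariate in self.schema:
            return self.schema[covariate].kind
        col = self.data[covariate]
        if isinstance(col.dtype, pd.CategoricalDtype):
            return "binary" if len(col.cat.categories) == 2 else "categorical"
        return "continuous"

    def check_linkage(self, sample_ids: Sequence[str]) -> None:
        """Raise unless annotation rows and count columns match exactly."""
        ann = set(self.data.index)
        cnt = set(sample_ids)
        only_ann = sorted(ann - cnt)
        only_cnt = sorted(cnt - ann)
        if only_ann or only_cnt:
            raise LinkageError(
                f"annotation/count sample mismatch: only in annotations {only_ann}; "
                f"only in counts {only_cnt}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, dialect: str = "tsv_matrix") -> RawCounts:
    """Read a count table.

    ``tsv_matrix`` expects columns ``probe_id, probe_class, <sample...>``;
    ``rcc_dir`` expects a directory of NanoString RCC lane files (one
    sample each) whose Code_Summary sections carry CodeClass labels.
    """
    path = Path(path)
    if dialect == "tsv_matrix":
        return _read_tsv_matrix(path)
    if dialect == "rcc_dir":
        return _read_rcc_dir(path)
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def _read_tsv_matrix(path: Path) -> RawCounts:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "probe_id" not in df.columns or "probe_class" not in df.columns:
        raise FormatError(f"{path}: need 'probe_id' and 'probe_class' columns")
    df = df.set_index("probe_id")
    probe_class = df.pop("probe_class").astype(str)
    counts = df.apply(pd.to_numeric, errors="raise")
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts present")
    return RawCounts(counts=counts, probe_class=probe_class)


def write_count_table(raw: RawCounts, path: str | Path) -> None:
    out = raw.counts.copy()
    out.insert(0, "probe_class", raw.probe_class)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def _read_rcc_dir(path: Path) -> RawCounts:
    files = sorted(path.glob("*.RCC")) + sorted(path.glob("*.rcc"))
    if not files:
        raise FormatError(f"{path}: no RCC lane files found")
    per_sample: dict[str, pd.Series] = {}
    probe_class: pd.Series | None = None
    for f in files:
        sample_id, counts, classes = _parse_rcc(f)
        if sample_id in per_sample:
            raise FormatError(f"duplicate sample id {sample_id!r} (file {f.name})")
        per_sample[sample_id] = counts
        if probe_class is None:
            probe_class = classes
        elif not classes.equals(probe_class):
            raise FormatError(f"{f.name}: probe set differs from previous lanes")
    counts_df = pd.DataFrame(per_sample)
    assert probe_class is not None
    return RawCounts(counts=counts_df, probe_class=probe_class)


def _parse_rcc(path: Path) -> tuple[str, pd.Series, pd.Series]:
    """Parse one RCC lane file -> (sample_id, counts, probe classes)."""
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("<") and not line.startswith("</"):
            current = line.strip("<>").strip()
            sections[current] = []
        elif line.startswith("</"):
            current = None
        elif current is not None:
            sections[current].append(line)
    if "Code_Summary" not in sections:
        raise FormatError(f"{path.name}: missing Code_Summary section")
    sample_id = path.stem
    for row in sections.get("Sample_Attributes", []):
        key, _, value = row.partition(",")
        if key == "ID" and value:
            sample_id = value
    body = sections["Code_Summary"]
    header = body[0].split(",")
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as exc:
        raise FormatError(f"{path.name}: malformed Code_Summary header") from exc
    names, classes, values = [], [], []
    for ln, row in enumerate(body[1:], start=2):
        parts = row.split(",")
        if len(parts) <= max(i_class, i_name, i_count):
            raise FormatError(f"{path.name}: malformed Code_Summary line {ln}")
        cls = RCC_CODECLASS_MAP.get(parts[i_class])
        if cls is None:
            raise FormatError(
                f"{path.name}: unknown CodeClass {parts[i_class]!r} (line {ln})"
            )
        names.append(parts[i_name])
        classes.append(cls)
        values.append(int(parts[i_count]))
    counts = pd.Series(values, index=pd.Index(names, name="probe_id"))
    return sample_id, counts, pd.Series(classes, index=counts.index)


def write_rcc_dir(raw: RawCounts, path: str | Path) -> None:
    """Write one RCC lane file per sample (round-trip partner of rcc_dir)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for sample in raw.sample_ids:
        lines = [
            "<Header>",
            "FileVersion,1.7",
            "SoftwareVersion,evpmircomp",
            "</Header>",
            "<Sample_Attributes>",
            f"ID,{sample}",
            "</Sample_Attributes>",
            "<Lane_Attributes>",
            "ID,1",
            "</Lane_Attributes>",
            "<Code_Summary>",
            "CodeClass,Name,Accession,Count",
        ]
        for probe in raw.probe_ids:
            cls = _RCC_CLASS_INV[raw.probe_class[probe]]
            lines.append(f"{cls},{probe},{probe},{int(raw.counts.at[probe, sample])}")
        lines.append("</Code_Summary>")
        (path / f"{sample}.RCC").write_text("\n".join(lines) + "\n")


def read_annotations(
    path: str | Path,
    schema: Mapping[str, CovariateSchema] | None = None,
    count_sample_ids: Sequence[str] | None = None,
) -> SampleAnnotations:
    """Read a sample-annotation CSV (must have a ``sample_id`` column).

    When ``count_sample_ids`` is given the two tables must cover the same
    samples; a mismatch raises :class:`LinkageError` listing the offending
    ids rather than dropping them silently.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    ann = SampleAnnotations(data=df, schema=dict(schema or {}))
    if count_sample_ids is not None:
        ann.check_linkage(count_sample_ids)
    return ann


def write_annotations(ann: SampleAnnotations, path: str | Path) -> None:
    out = ann.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# normalization & QC
# ---------------------------------------------------------------------------


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def normalize_positive_controls(
    raw: RawCounts, summary: str = "geomean"
) -> NormalizedCounts:
    """Rescale each lane so its positive controls match the cohort average.

    The per-sample factor is ``mean_over_samples(g) / g_sample`` where ``g``
    summarizes the positive-control counts of a lane (geometric mean by
    default, ``summary="sum"`` as a dialect).  Endogenous and negative
    counts are multiplied by the factor; negative controls are carried on
    both the raw and normalized scales for downstream detection calls.
    """
    pos = raw.positive
    if pos.shape[0] < 1:
        raise NormalizationError("no positive-control probes present")
    if summary not in ("geomean", "sum"):
        raise ConfigurationError(f"unknown positive-control summary {summary!r}")
    zero_lane = (pos <= 0).all(axis=0)
    if zero_lane.any():
        bad = zero_lane.index[zero_lane].tolist()
        raise NormalizationError(f"all-zero positive controls in samples {bad}")
    vals = pos.to_numpy(dtype=float)
    if summary == "geomean":
        if (vals <= 0).any():
            # geometric mean over the positive (nonzero) counts per lane
            g = np.array(
                [_geometric_mean(col[col > 0]) for col in vals.T], dtype=float
            )
        else:
            g = np.exp(np.mean(np.log(vals), axis=0))
    else:
        g = vals.sum(axis=0)
    factors = pd.Series(g.mean() / g, index=pos.columns, name="norm_factor")
    endo = raw.endogenous.astype(float).mul(factors, axis=1)
    raw_neg = raw.negative.astype(float)
    neg = raw_neg.mul(factors, axis=1)
    return NormalizedCounts(
        counts=endo, norm_factors=factors, negatives=neg, raw_negatives=raw_neg
    )


def write_normalized(norm: NormalizedCounts, path: str | Path) -> None:
    out = norm.counts.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    meta = Path(path).with_suffix(".factors.tsv")
    df = norm.norm_factors.rename("norm_factor").to_frame()
    df.index.name = "sample_id"
    df.to_csv(meta, sep="\t")


def spikein_qc(
    raw: RawCounts, spikein_probe_id: str, tolerance: float = 4.0
) -> QCReport:
    """Flag samples whose spike-in recovery deviates from the cohort median.

    A sample is ``warn`` when its spike-in count differs from the cohort
    median by more than ``tolerance``-fold in either direction.  Also
    reports per-sample positive-control linearity (Pearson r of log2 counts
    against the log2 titration ladder) as a secondary QC statistic.
    """
    if spikein_probe_id not in raw.counts.index:
        raise ConfigurationError(f"spike-in probe {spikein_probe_id!r} not present")
    if tolerance <= 1:
        raise ConfigurationError("tolerance must exceed 1 (fold-change)")
    spike = raw.counts.loc[spikein_probe_id].astype(float)
    med = float(spike.median())
    if med <= 0:
        flags = pd.Series("warn", index=spike.index)
    else:
        ratio = spike / med
        bad = (ratio > tolerance) | (ratio < 1.0 / tolerance)
        flags = pd.Series(np.where(bad, "warn", "pass"), index=spike.index)
    pos = raw.positive.astype(float)
    lin = pd.Series(np.nan, index=spike.index, dtype=float)
    if pos.shape[0] >= 3:
        # positive controls come ordered from highest to lowest titration step
        ladder = np.arange(pos.shape[0], dtype=float)
        for s in pos.columns:
            y = np.log2(pos[s].to_numpy() + 1.0)
            if np.std(y) > 0:
                lin[s] = float(np.corrcoef(ladder, y)[0, 1])
    return QCReport(spikein_counts=spike, flags=flags, positive_linearity=lin)


def write_qc(report: QCReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
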