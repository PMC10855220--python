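"""Bivariate covariate screening against composition measures.

Each candidate covariate is tested against each composition measure with a
nonparametric test matched to its type: Spearman correlation for
continuous covariates, two-sided Wilcoxon rank-sum for binary ones (exact
enumeration when both groups have <= 10 observations and no ties, normal
approximation with tie correction otherwise), and Kruskal-Wallis for three
or more categories.  Covariates associated with *any* measure at p < 0.1
are carried into the adjusted models as potential confounders or
precision variables.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .nanostring_io import SampleAnnotations

MEASURES = ("total_counts_log2", "richness", "evenness")

#: Candidate covariates screened for each sample type (the cohort's
#: pre-specified lists); the selection itself is always recomputed.
DEFAULT_CANDIDATES = {
    "plasma": [
        "maternal_age",
        "pre_pregnancy_bmi",
        "weight_status",
        "parity",
        "infant_sex",
        "gestational_age_collection",
        "time_of_day",
    ],
    "milk": [
        "maternal_age",
        "pre_pregnancy_bmi",
        "weight_status",
        "gestational_weight_gain",
        "gestational_age_delivery",
        "parity",
        "infant_sex",
        "delivery_mode",
        "infant_age_days",
        "time_of_day",
    ],
}

#: Adjustment sets the study itself arrived at (documented defaults for
#: reproduction runs; `select_covariates` recomputes them from data).
STUDY_SELECTED = {
    "plasma": ["time_of_day", "maternal_age", "parity"],
    "milk": [
        "gestational_weight_gain",
        "parity",
        "infant_sex",
        "delivery_mode",
        "infant_age_days",
    ],
}


@dataclass
class ScreeningResult:
    covariate: str
    measure: str
    test: str  # "spearman" | "ranksum" | "kruskal"
    statistic: float
    p: float
    n: int


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p via the Mann-Whitney U null distribution."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return float(res.statistic), float(res.pvalue)


def bivariate_screen(
    comp: pd.DataFrame,
    ann: SampleAnnotations,
    covariate: str,
    measure: str,
) -> ScreeningResult:
    """Test one covariate against one composition measure.

    Pairs with a missing covariate or measure value are dropped listwise
    for this test only.
    """
    if measure not in comp.columns:
        raise KeyError(f"measure {measure!r} not in composition table")
    if covariate not in ann.data.columns:
        raise KeyError(f"covariate {covariate!r} not in annotations")
    y = comp[measure]
    x = ann.data[covariate].reindex(y.index)
    keep = y.notna() & x.notna()
    y, x = y[keep].astype(float), x[keep]
    n = int(keep.sum())
    kind = ann.kind_of(covariate)

    if kind == "continuous":
        xv = x.to_numpy(dtype=float)
        if np.unique(xv).size < 2 or np.unique(y.to_numpy()).size < 2:
            raise DegenerateInputError(
                f"{covariate!r} or {measure!r} constant after missingness"
            )
        rho, p = stats.spearmanr(xv, y.to_numpy())
        return ScreeningResult(covariate, measure, "spearman", float(rho), float(p), n)

    groups = [
        y[x.astype(str) == lvl].to_numpy()
        for lvl in pd.Categorical(x).categories
        if (x.astype(str) == lvl).any()
    ]
    if len(groups) < 2:
        raise DegenerateInputError(f"{covariate!r} constant after missingness")

    if kind == "binary" or len(groups) == 2:
        a, b = groups
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        if len(a) <= 10 and len(b) <= 10 and no_ties:
            stat, p = _exact_ranksum_p(a, b)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        return ScreeningResult(covariate, measure, "ranksum", stat, p, n)

    if np.unique(np.concatenate(groups)).size == 1:
        raise DegenerateInputError(f"{measure!r} constant in all groups")
    try:
        h, p = stats.kruskal(*groups)
    except ValueError as exc:  # all values identical
        raise DegenerateInputError(str(exc)) from exc
    return ScreeningResult(covariate, measure, "kruskal", float(h), float(p), n)


def screen_all(
    comp: pd.DataFrame,
    ann: SampleAnnotations,
    covariates: Sequence[str],
    measures: Sequence[str] = MEASURES,
) -> list[ScreeningResult]:
    """Screen every candidate covariate against every measure.

    Degenerate covariate/measure pairs are skipped (they carry no
    selection information) rather than aborting the screen.
    """
    out: list[ScreeningResult] = []
    for cov in covariates:
        for m in measures:
            try:
                out.append(bivariate_screen(comp, ann, cov, m))
            except DegenerateInputError:
                continue
    return out


def select_covariates(
    results: Iterable[ScreeningResult], alpha: float = 0.1
) -> list[str]:
    """Covariates with p < alpha against ANY measure, in input order."""
    selected: list[str] = []
    for r in results:
        if r.p < alpha and r.covariate not in selected:
            selected.append(r.covariate)
    return selected


def screening_table(results: Iterable[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])
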