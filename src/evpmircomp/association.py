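"""Adjusted association models and the two-stage per-miRNA procedure.

Composition outcomes (log2 total counts, richness, evenness) are modeled
with ordinary least squares and with Huber robust linear regression
(c = 1.345, MAD scale), adjusting for the screened covariates.  Individual
miRNAs are routed by their detection rate: probes detected in fewer than
20% of samples are excluded, probes detected in 20-60% are modeled as
binary detect/non-detect, and probes detected in more than 60% as
continuous log2 counts.

The two-stage scan first regresses richness or evenness on each routed
miRNA (robust linear regression, Bonferroni gate at adjusted p < 0.05) and
then, for a factor associated with that measure, fits adjusted models of
each gated miRNA on the factor -- robust linear for continuous-mode
probes, bounded-influence robust logistic (Cantoni-Ronchetti
quasi-likelihood, Huber downweighting of Pearson residuals beyond c) for
binary-mode probes -- with Storey q-values across the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .composition import DetectionMatrix
from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
    EvpMirCompError,
    SeparationError,
)
from .multiple_testing import bonferroni, storey_qvalues
from .nanostring_io import NormalizedCounts, SampleAnnotations

HUBER_C = 1.345
#: pseudocount for log2 transforms of individual probe counts (a probe can
#: be zero in some samples even when its detection rate exceeds 60%)
LOG2_PSEUDOCOUNT = 1.0


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One adjusted model: outcome ~ predictor + covariates.

    ``exclude`` is a pandas query over the model frame naming rows to drop
    before fitting (e.g. ``"pre_pregnancy_bmi < 18.5"`` when weight status
    enters as a categorical predictor).
    """

    outcome: str
    predictor: str
    covariates: tuple[str, ...] = ()
    exclude: str | None = None

    def __post_init__(self) -> None:
        if self.predictor in self.covariates:
            raise ConfigurationError(
                f"predictor {self.predictor!r} duplicated among covariates"
            )


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    covariates: tuple[str, ...]
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    method: str  # "ols" | "robust_lm" | "robust_logistic"


def _expand_column(col: pd.Series, name: str) -> pd.DataFrame:
    """Reference-coded numeric expansion of one model column."""
    if isinstance(col.dtype, pd.CategoricalDtype):
        cats = [c for c in col.cat.categories if (col == c).any()]
        if len(cats) < 2:
            raise DegenerateInputError(f"{name!r} is constant after exclusions")
        out = pd.DataFrame(index=col.index)
        for c in cats[1:]:
            out[f"{name}[{c}]"] = (col == c).astype(float)
        out.loc[col.isna(), :] = np.nan
        return out
    return pd.DataFrame({name: pd.to_numeric(col, errors="raise")})


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, str]:
    """Assemble (y, X, predictor column) with listwise deletion.

    X includes an intercept column ``const``; categorical terms are
    reference-coded against their first observed level.  Returns the name
    of the design column carrying the predictor-of-interest contrast.
    """
    used = [spec.outcome, spec.predictor, *spec.covariates]
    missing = [c for c in used if c not in data.columns]
    if missing:
        raise ConfigurationError(f"model variables not in data: {missing}")
    frame = data[used].copy()
    if spec.exclude:
        frame = frame[~data.eval(spec.exclude).reindex(frame.index).fillna(False)]
    frame = frame.dropna()
    if frame.empty:
        raise DegenerateInputError("no complete rows after exclusions")
    # drop unused categories so reference coding reflects the analysed rows
    for c in frame.columns:
        if isinstance(frame[c].dtype, pd.CategoricalDtype):
            frame[c] = frame[c].cat.remove_unused_categories()
    y = pd.to_numeric(frame[spec.outcome], errors="raise")
    blocks = [pd.DataFrame({"const": np.ones(len(frame))}, index=frame.index)]
    pred_block = _expand_column(frame[spec.predictor], spec.predictor)
    blocks.append(pred_block)
    for cov in spec.covariates:
        blocks.append(_expand_column(frame[cov], cov))
    X = pd.concat(blocks, axis=1)
    pred_col = pred_block.columns[0]
    _check_rank(X)
    return y, X, pred_col


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # report which columns are linear combinations of the preceding ones
        collinear = []
        for j in range(1, mat.shape[1]):
            if np.linalg.matrix_rank(mat[:, : j + 1]) <= np.linalg.matrix_rank(
                mat[:, :j]
            ):
                collinear.append(X.columns[j])
        raise DegenerateInputError(f"rank-deficient design; collinear: {collinear}")


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------


def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> AssociationResult:
    """Least squares with t-based two-sided p and 95% CI."""
    y, X, pred_col = build_design(data, spec)
    n = len(y)
    if n <= X.shape[1]:
        raise DegenerateInputError(
            f"n={n} does not exceed the {X.shape[1]} model parameters"
        )
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index(pred_col)
    ci = fit.conf_int(alpha=0.05)
    return AssociationResult(
        outcome=spec.outcome,
        predictor=spec.predictor,
        covariates=spec.covariates,
        estimate=float(fit.params[j]),
        ci_low=float(ci[j, 0]),
        ci_high=float(ci[j, 1]),
        p=float(fit.pvalues[j]),
        n=n,
        method="ols",
    )


def fit_robust_lm(
    spec: ModelSpec, data: pd.DataFrame, tuning_c: float = HUBER_C
) -> AssociationResult:
    """Huber M-estimate via IRLS with MAD scale; asymptotic robust CI.

    Weights are 1 for residuals within ``tuning_c`` scale units and decay
    as c*s/|u| beyond; the scale is the MAD of residuals / 0.6745,
    re-estimated each iteration.  Reduces to OLS on clean data.
    """
    y, X, pred_col = build_design(data, spec)
    n = len(y)
    if n <= X.shape[1]:
        raise DegenerateInputError(
            f"n={n} does not exceed the {X.shape[1]} model parameters"
        )
    model = sm.RLM(y.to_numpy(), X.to_numpy(), M=sm.robust.norms.HuberT(t=tuning_c))
    try:
        fit = model.fit(scale_est="mad", conv="coefs", tol=1e-8, maxiter=50)
    except Exception as exc:  # pragma: no cover - statsmodels internal failure
        raise ConvergenceError(f"robust linear fit failed: {exc}") from exc
    j = list(X.columns).index(pred_col)
    est = float(fit.params[j])
    se = float(fit.bse[j])
    # t reference with n - p df: the asymptotic normal is anti-conservative
    # in the far tails at pilot-study sample sizes
    dof = n - X.shape[1]
    tq = stats.t.ppf(0.975, dof)
    p = float(2 * stats.t.sf(abs(est / se), dof)) if se > 0 else 0.0
    return AssociationResult(
        outcome=spec.outcome,
        predictor=spec.predictor,
        covariates=spec.covariates,
        estimate=est,
        ci_low=est - tq * se,
        ci_high=est + tq * se,
        p=p,
        n=n,
        method="robust_lm",
    )


# ---------------------------------------------------------------------------
# robust logistic regression (bounded-influence quasi-likelihood)
# ---------------------------------------------------------------------------


def _huber_psi(r: np.ndarray, c: float) -> np.ndarray:
    return np.clip(r, -c, c)


def _cr_score(beta: np.ndarray, X: np.ndarray, y: np.ndarray, c: float) -> np.ndarray:
    """Cantoni-Ronchetti estimating function for a logistic GLM.

    sum_i [psi_c(r_i) - a_i(beta)] * sqrt(v_i) * x_i with Pearson residual
    r_i = (y_i - mu_i)/sqrt(v_i) and the Fisher-consistency correction
    a_i = E[psi_c(r_i)] under the model.
    """
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    v = mu * (1 - mu)
    sv = np.sqrt(v)
    r = (y - mu) / sv
    r1 = (1 - mu) / sv  # residual if y = 1
    r0 = -mu / sv  # residual if y = 0
    a = _huber_psi(r1, c) * mu + _huber_psi(r0, c) * (1 - mu)
    w = _huber_psi(r, c) - a
    return X.T @ (w * sv)


def fit_robust_logistic(
    spec: ModelSpec,
    data: pd.DataFrame,
    tuning_c: float = HUBER_C,
    plain_ml: bool = False,
) -> AssociationResult:
    """Bounded-influence robust logistic fit (log-odds scale).

    Solves the Huber-downweighted quasi-likelihood estimating equations
    with a Fisher-consistency correction, starting from the ML solution;
    the covariance is the asymptotic sandwich M^-1 Q M^-T.  With
    ``plain_ml=True`` an ordinary ML fit with sandwich (HC) standard
    errors is returned instead.  Odds ratios are exp(estimate).
    """
    y, X, pred_col = build_design(data, spec)
    yv = y.to_numpy(dtype=float)
    classes = np.unique(yv)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ConfigurationError("logistic outcome must be coded 0/1")
    if classes.size < 2:
        raise DegenerateInputError("one-class outcome: logistic fit undefined")
    Xv = X.to_numpy(dtype=float)
    n, k = Xv.shape
    if n <= k:
        raise DegenerateInputError(f"n={n} does not exceed the {k} model parameters")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            ml = sm.Logit(yv, Xv).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise SeparationError(f"ML logistic fit failed: {exc}") from exc
    # complete separation sends coefficients to +/-inf; quasi-complete
    # separation (a pure covariate class) does the same for one contrast.
    # Log-odds beyond ~15 (OR > 3e6) only arise from (quasi-)separation.
    if not ml.mle_retvals.get("converged", True) or np.max(np.abs(ml.params)) > 15:
        raise SeparationError("complete or quasi-complete separation detected")

    if plain_ml:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rob = sm.Logit(yv, Xv).fit(disp=0, cov_type="HC0")
        params, cov = rob.params, rob.cov_params()
        method = "robust_logistic"  # ML point estimate, sandwich errors
    else:
        sol = optimize.root(
            _cr_score, ml.params, args=(Xv, yv, tuning_c), method="hybr",
            options={"xtol": 1e-10},
        )
        if not sol.success:
            raise ConvergenceError(f"robust logistic did not converge: {sol.message}")
        params = sol.x
        cov = _cr_covariance(params, Xv, yv, tuning_c)
        method = "robust_logistic"

    j = list(X.columns).index(pred_col)
    est = float(params[j])
    se = float(np.sqrt(cov[j, j]))
    dof = n - k
    tq = stats.t.ppf(0.975, dof)
    p = float(2 * stats.t.sf(abs(est / se), dof)) if se > 0 else 0.0
    return AssociationResult(
        outcome=spec.outcome,
        predictor=spec.predictor,
        covariates=spec.covariates,
        estimate=est,
        ci_low=est - tq * se,
        ci_high=est + tq * se,
        p=p,
        n=n,
        method=method,
    )


def _cr_covariance(
    beta: np.ndarray, X: np.ndarray, y: np.ndarray, c: float
) -> np.ndarray:
    """Asymptotic sandwich covariance M^-1 Q M^-T / 1 for the CR estimator."""
    n, k = X.shape
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    v = mu * (1 - mu)
    sv = np.sqrt(v)
    r1 = (1 - mu) / sv
    r0 = -mu / sv
    psi1 = _huber_psi(r1, c)
    psi0 = _huber_psi(r0, c)
    a = psi1 * mu + psi0 * (1 - mu)
    e_psi2 = psi1**2 * mu + psi0**2 * (1 - mu)
    # Q = sum Var(score contribution): (E[psi^2] - a^2) * v * x x^T
    Q = (X * ((e_psi2 - a**2) * v)[:, None]).T @ X
    # M = -d(score)/d(beta), by central finite differences
    M = np.empty((k, k))
    h = 1e-6 * np.maximum(1.0, np.abs(beta))
    for j in range(k):
        bp, bm = beta.copy(), beta.copy()
        bp[j] += h[j]
        bm[j] -= h[j]
        M[:, j] = -(_cr_score(bp, X, y, c) - _cr_score(bm, X, y, c)) / (2 * h[j])
    Minv = np.linalg.pinv(M)
    return Minv @ Q @ Minv.T


# ---------------------------------------------------------------------------
# detection-rate routing and per-miRNA predictors
# ---------------------------------------------------------------------------


@dataclass
class MiRnaRouting:
    probe_id: str
    detection_rate: float
    mode: str  # "excluded" | "binary" | "continuous"


def route_mirnas(
    det: DetectionMatrix, low: float = 0.20, high: float = 0.60
) -> list[MiRnaRouting]:
    """Route each probe by detection rate (boundaries inclusive for binary)."""
    rates = det.detection_rates
    out = []
    for probe, rate in rates.items():
        if rate < low:
            mode = "excluded"
        elif rate <= high:
            mode = "binary"
        else:
            mode = "continuous"
        out.append(MiRnaRouting(str(probe), float(rate), mode))
    return out


def routing_table(routing: Sequence[MiRnaRouting]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.probe_id, r.detection_rate, r.mode) for r in routing],
        columns=["probe_id", "detection_rate", "mode"],
    )


def mirna_predictor(
    probe_id: str,
    mode: str,
    norm: NormalizedCounts,
    det: DetectionMatrix,
    pseudocount: float = LOG2_PSEUDOCOUNT,
) -> pd.Series:
    """Model variable for one probe: 0/1 detect call or log2(count + pc)."""
    if mode == "binary":
        return det.detected.loc[probe_id].astype(float)
    if mode == "continuous":
        return np.log2(norm.counts.loc[probe_id] + pseudocount)
    raise ConfigurationError(f"probe {probe_id!r} routed as {mode!r}; cannot model")


# ---------------------------------------------------------------------------
# two-stage per-miRNA scans
# ---------------------------------------------------------------------------


def composition_mirna_scan(
    measure: str,
    comp: pd.DataFrame,
    norm: NormalizedCounts,
    det: DetectionMatrix,
    routing: Sequence[MiRnaRouting] | None = None,
    alpha: float = 0.05,
    pseudocount: float = LOG2_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Stage 1: regress ``measure`` on each routed miRNA (robust linear).

    Returns one row per probe attempted, with columns ``probe_id, mode,
    detection_rate, estimate, p, p_bonferroni, flagged, status``; the
    Bonferroni denominator is the number of fits that succeeded.
    Degenerate probes (constant predictor, failed fit) are recorded with a
    status and excluded from the multiplicity count.
    """
    if measure not in ("richness", "evenness"):
        raise ConfigurationError(f"scan measure must be richness/evenness, got {measure!r}")
    if comp[measure].notna().sum() < 3:
        raise DegenerateInputError(f"measure {measure!r} defined for < 3 samples")
    routing = routing if routing is not None else route_mirnas(det)
    rows = []
    for r in routing:
        if r.mode == "excluded":
            continue
        x = mirna_predictor(r.probe_id, r.mode, norm, det, pseudocount)
        frame = pd.DataFrame({measure: comp[measure], "mirna": x})
        rec = {
            "probe_id": r.probe_id,
            "mode": r.mode,
            "detection_rate": r.detection_rate,
            "estimate": np.nan,
            "p": np.nan,
            "status": "ok",
        }
        try:
            if frame.dropna()["mirna"].nunique() < 2:
                raise DegenerateInputError("constant predictor")
            res = fit_robust_lm(ModelSpec(outcome=measure, predictor="mirna"), frame)
            rec["estimate"], rec["p"] = res.estimate, res.p
        except EvpMirCompError as exc:
            rec["status"] = f"degenerate: {exc}"
        rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        return table.reindex(
            columns=["probe_id", "mode", "detection_rate", "estimate", "p",
                     "p_bonferroni", "flagged", "status"]
        )
    ok = table["status"] == "ok"
    m = int(ok.sum())
    table["p_bonferroni"] = np.nan
    if m:
        table.loc[ok, "p_bonferroni"] = bonferroni(table.loc[ok, "p"].to_numpy(), m)
    table["flagged"] = table["p_bonferroni"] < alpha
    return table


def posthoc_factor_scan(
    factor: str,
    flagged_mirnas: Sequence[str],
    covariates: Sequence[str],
    ann: SampleAnnotations,
    norm: NormalizedCounts,
    det: DetectionMatrix,
    routing: Sequence[MiRnaRouting] | None = None,
    q_threshold: float = 0.05,
    pseudocount: float = LOG2_PSEUDOCOUNT,
    exclude: str | None = None,
) -> pd.DataFrame:
    """Stage 2: adjusted per-miRNA models of each flagged probe on a factor.

    Continuous-mode probes: robust linear fit of log2 counts on the factor
    plus covariates.  Binary-mode probes: robust logistic of the detect
    call.  Storey q-values are computed across the scan's successful fits
    and probes with q < ``q_threshold`` are marked significant.  An empty
    flagged set returns an empty table.
    """
    routing = routing if routing is not None else route_mirnas(det)
    modes = {r.probe_id: r.mode for r in routing}
    cols = ["probe_id", "mode", "estimate", "ci_low", "ci_high", "p", "n",
            "method", "status", "q", "significant"]
    rows = []
    for probe in flagged_mirnas:
        mode = modes.get(probe)
        rec = {
            "probe_id": probe, "mode": mode, "estimate": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "p": np.nan, "n": 0, "method": "", "status": "ok",
        }
        if mode is None:
            rec["status"] = "degenerate: probe not routed"
            rows.append(rec)
            continue
        if mode == "excluded":
            rec["status"] = "degenerate: detection rate below 20%"
            rows.append(rec)
            continue
        x = mirna_predictor(probe, mode, norm, det, pseudocount)
        frame = ann.data.copy()
        frame["mirna"] = x.reindex(frame.index)
        spec = ModelSpec(
            outcome="mirna", predictor=factor,
            covariates=tuple(covariates), exclude=exclude,
        )
        try:
            if mode == "binary":
                res = fit_robust_logistic(spec, frame)
            else:
                res = fit_robust_lm(spec, frame)
            rec.update(
                estimate=res.estimate, ci_low=res.ci_low, ci_high=res.ci_high,
                p=res.p, n=res.n, method=res.method,
            )
        except EvpMirCompError as exc:
            rec["status"] = f"degenerate: {exc}"
        rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        return table.reindex(columns=cols)
    ok = table["status"] == "ok"
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = storey_qvalues(table.loc[ok, "p"].to_numpy()).q
    table["significant"] = table["q"] < q_threshold
    return table[cols]


def results_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "predictor": r.predictor,
                "covariates": ",".join(r.covariates),
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n": r.n,
                "method": r.method,
            }
            for r in results
        ]
    )
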