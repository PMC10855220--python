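"""Synthetic nCounter-style cohorts with known injected effects.

Emulates a small mother-infant cohort profiled on a ~800-probe miRNA panel:
heavily zero-inflated endogenous counts whose probe-specific abundances span
several orders of magnitude, Poisson negative-control background, a fixed
positive-control titration ladder, and lane-specific scaling that the
positive-control normalization is expected to absorb.  Covariates are drawn
from the cohort's published marginals (maternal age 32.6 +/- 4.0 y, 25.9%
cesarean deliveries, 44.4% male infants, 22.2% pre-pregnancy BMI > 25,
half of blood draws in the afternoon).

Effects are injected multiplicatively on the log2 scale: an
:class:`EffectSpec` with ``log2_effect = e`` multiplies the targeted probe
means by ``2**(e * x)`` where ``x`` is the covariate's design value
(0/1 indicator for a binary covariate, mean-centered value for a continuous
one), before lane scaling.  A ``total_counts`` effect targets every
endogenous probe, so the downstream log2-total estimate should recover
``e``; a ``mirna_subset`` effect perturbs only the listed probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .nanostring_io import CovariateSchema, RawCounts, SampleAnnotations

# Cohort marginals (means/SDs and category proportions of the study design).
DEFAULT_COVARIATE_MARGINALS: dict[str, dict] = {
    "maternal_age": {"dist": "normal", "mean": 32.6, "sd": 4.0},
    "weight_status": {
        "dist": "categorical",
        "levels": ["normal", "under", "over"],
        "p": [0.722, 0.056, 0.222],
    },
    # BMI is drawn conditionally on weight_status (truncated normal) so the
    # continuous and categorical views of weight agree row by row.
    "pre_pregnancy_bmi": {"dist": "bmi_conditional", "mean": 23.9, "sd": 4.9},
    "gestational_weight_gain": {"dist": "normal", "mean": 34.8, "sd": 18.9},
    "gestational_age_delivery": {"dist": "normal", "mean": 39.2, "sd": 1.5},
    "gestational_age_collection": {"dist": "normal", "mean": 28.8, "sd": 2.8},
    "infant_age_days": {"dist": "normal", "mean": 42.7, "sd": 5.6},
    "parity": {
        "dist": "categorical",
        "levels": ["primiparous", "multiparous"],
        "p": [0.5, 0.5],
    },
    "delivery_mode": {
        "dist": "categorical",
        "levels": ["vaginal", "cesarean"],
        "p": [0.741, 0.259],
    },
    "infant_sex": {
        "dist": "categorical",
        "levels": ["female", "male"],
        "p": [0.556, 0.444],
    },
    "time_of_day": {
        "dist": "categorical",
        "levels": ["morning", "afternoon"],
        "p": [0.5, 0.5],
    },
}

_BMI_BOUNDS = {"under": (14.0, 18.5), "normal": (18.5, 25.0), "over": (25.0, 45.0)}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated cohort.

    Count-model knobs: ``background_mean`` is the negative-control Poisson
    mean; a ``frac_low_abundance`` fraction of endogenous probes sit near or
    below background (log-uniform means in [0.02, 1.2] x background) while
    the rest span up to ~3000 x background; per-probe NB dispersions are
    uniform on ``dispersion_range``; lanes carry log-normal scale factors
    (sigma ``lane_sigma``); each sample additionally carries a biological
    abundance factor on endogenous probes only (log2-normal, SD
    ``sample_sigma_log2``) so that log2 totals are right-skewed and spread
    realistically even after normalization.
    """

    n_samples: int
    n_endogenous: int = 798
    n_pos_controls: int = 6
    n_neg_controls: int = 6
    seed: int = 0
    covariate_marginals: Mapping[str, dict] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS)
    )
    background_mean: float = 10.0
    frac_low_abundance: float = 0.6
    dispersion_range: tuple[float, float] = (0.2, 1.0)
    lane_sigma: float = 0.25
    sample_sigma_log2: float = 1.0
    pos_control_top: float = 32000.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_endogenous < 1 or self.n_pos_controls < 2 or self.n_neg_controls < 2:
            raise ConfigurationError("need >=1 endogenous and >=2 of each control class")
        if not 0.0 <= self.frac_low_abundance <= 1.0:
            raise ConfigurationError("frac_low_abundance must be in [0, 1]")
        for name, marg in self.covariate_marginals.items():
            if marg["dist"] == "categorical":
                p = marg["p"]
                if any(not 0.0 <= pi <= 1.0 for pi in p) or not math.isclose(
                    sum(p), 1.0, abs_tol=1e-9
                ):
                    raise ConfigurationError(
                        f"covariate {name!r}: proportions must lie in [0,1] and sum to 1"
                    )

    def probe_ids(self) -> tuple[list[str], list[str], list[str]]:
        endo = [f"hsa-miR-sim-{i:04d}" for i in range(1, self.n_endogenous + 1)]
        pos = [f"POS_{chr(ord('A') + i)}" for i in range(self.n_pos_controls)]
        neg = [f"NEG_{chr(ord('A') + i)}" for i in range(self.n_neg_controls)]
        return endo, pos, neg

    def schema(self) -> dict[str, CovariateSchema]:
        out: dict[str, CovariateSchema] = {}
        for name, marg in self.covariate_marginals.items():
            if marg["dist"] == "categorical":
                kind = "binary" if len(marg["levels"]) == 2 else "categorical"
                out[name] = CovariateSchema(name, kind, tuple(marg["levels"]))
            else:
                out[name] = CovariateSchema(name, "continuous")
        return out


@dataclass(frozen=True)
class EffectSpec:
    """One injected covariate effect on the count model (log2 scale)."""

    target: str  # "total_counts" | "mirna_subset"
    covariate: str
    log2_effect: float
    affected_probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.target not in ("total_counts", "mirna_subset"):
            raise ConfigurationError(f"unknown effect target {self.target!r}")
        if not math.isfinite(self.log2_effect):
            raise ConfigurationError("log2_effect must be finite")
        if self.target == "mirna_subset" and not self.affected_probes:
            raise ConfigurationError("mirna_subset effect needs affected_probes")
        if self.target == "total_counts" and self.affected_probes:
            raise ConfigurationError("total_counts effect takes no probe list")


# ---------------------------------------------------------------------------
# cohort covariates
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec) -> SampleAnnotations:
    """Draw the covariate table for one cohort (deterministic under seed)."""
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_samples
    cols: dict[str, np.ndarray | pd.Categorical] = {}
    marginals = spec.covariate_marginals
    # weight status first so BMI can condition on it
    order = sorted(marginals, key=lambda k: marginals[k]["dist"] == "bmi_conditional")
    for name in order:
        marg = marginals[name]
        if marg["dist"] == "normal":
            cols[name] = rng.normal(marg["mean"], marg["sd"], size=n)
        elif marg["dist"] == "categorical":
            draws = rng.choice(len(marg["levels"]), size=n, p=marg["p"])
            cols[name] = pd.Categorical.from_codes(
                draws, categories=marg["levels"]
            )
        elif marg["dist"] == "bmi_conditional":
            status = cols.get("weight_status")
            if status is None:
                cols[name] = rng.normal(marg["mean"], marg["sd"], size=n)
            else:
                cols[name] = _bmi_given_status(
                    np.asarray(pd.Categorical(status).astype(str)),
                    marg["mean"],
                    marg["sd"],
                    rng,
                )
        else:
            raise ConfigurationError(f"unknown marginal {marg['dist']!r} for {name!r}")
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    df = pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))
    return SampleAnnotations(data=df, schema=spec.schema())


def _bmi_given_status(
    status: np.ndarray, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal BMI draw within each weight-status band."""
    out = np.empty(status.shape[0])
    for cat, (lo, hi) in _BMI_BOUNDS.items():
        mask = status == cat
        k = int(mask.sum())
        if k == 0:
            continue
        a, b = stats.norm.cdf([lo, hi], loc=mean, scale=sd)
        u = rng.uniform(a, b, size=k)
        out[mask] = stats.norm.ppf(u, loc=mean, scale=sd)
    return out


def covariate_design_values(ann: SampleAnnotations, covariate: str) -> np.ndarray:
    """Numeric design encoding of a covariate for effect injection.

    Binary categorical -> 0/1 indicator of the non-reference level;
    continuous -> mean-centered values (so 2**(e*x) stays bounded).
    """
    if covariate not in ann.data.columns:
        raise ConfigurationError(f"unknown covariate {covariate!r}")
    col = ann.data[covariate]
    if isinstance(col.dtype, pd.CategoricalDtype):
        if len(col.cat.categories) != 2:
            raise ConfigurationError(
                f"effects on {covariate!r}: only binary categorical supported"
            )
        return (col == col.cat.categories[1]).to_numpy(dtype=float)
    x = col.to_numpy(dtype=float)
    return x - np.nanmean(x)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def generate_counts(
    annotations: SampleAnnotations,
    spec: CohortSpec,
    effects: Sequence[EffectSpec] = (),
) -> RawCounts:
    """Draw the probes x samples count matrix for a cohort.

    Endogenous probes are negative binomial around probe-specific means
    (modulated by per-sample biology, injected effects, and the lane
    factor); negative controls are Poisson around ``background_mean`` times
    the lane factor; positive controls follow a fixed 4-fold titration
    ladder scaled by the lane factor.  Deterministic under ``spec.seed``.
    """
    if len(annotations.data) != spec.n_samples:
        raise ConfigurationError(
            f"annotations have {len(annotations.data)} rows, spec expects {spec.n_samples}"
        )
    endo_ids, pos_ids, neg_ids = spec.probe_ids()
    probe_rng = np.random.default_rng([spec.seed, 1])
    noise_rng = np.random.default_rng([spec.seed, 2])
    n = spec.n_samples
    bg = spec.background_mean

    # probe-level parameters (independent of the covariate draw)
    n_low = int(round(spec.frac_low_abundance * spec.n_endogenous))
    low_means = bg * 10 ** probe_rng.uniform(
        np.log10(0.02), np.log10(1.2), size=n_low
    )
    high_means = bg * 10 ** probe_rng.uniform(
        np.log10(1.2), np.log10(3000.0), size=spec.n_endogenous - n_low
    )
    base_means = np.concatenate([low_means, high_means])
    probe_rng.shuffle(base_means)
    dispersion = probe_rng.uniform(*spec.dispersion_range, size=spec.n_endogenous)

    # per-sample modifiers
    lane = np.exp(noise_rng.normal(0.0, spec.lane_sigma, size=n))
    biology = 2.0 ** noise_rng.normal(0.0, spec.sample_sigma_log2, size=n)

    mean_matrix = np.outer(base_means, biology)  # endo probes x samples
    endo_index = {p: i for i, p in enumerate(endo_ids)}
    for eff in effects:
        x = covariate_design_values(annotations, eff.covariate)
        x = np.nan_to_num(x, nan=0.0)
        mult = 2.0 ** (eff.log2_effect * x)
        if eff.target == "total_counts":
            mean_matrix *= mult[None, :]
        else:
            unknown = [p for p in eff.affected_probes if p not in endo_index]
            if unknown:
                raise ConfigurationError(f"unknown probe ids in effect: {unknown}")
            rows = [endo_index[p] for p in eff.affected_probes]
            mean_matrix[rows, :] *= mult[None, :]
    mean_matrix = mean_matrix * lane[None, :]

    # NB draws: shape r = 1/alpha, p = r / (r + mu)
    r = (1.0 / dispersion)[:, None]
    p = r / (r + np.maximum(mean_matrix, 1e-12))
    endo_counts = noise_rng.negative_binomial(r, p)

    neg_counts = noise_rng.poisson(bg * lane[None, :], size=(spec.n_neg_controls, n))
    ladder = spec.pos_control_top * 4.0 ** -np.arange(spec.n_pos_controls)
    pos_counts = noise_rng.poisson(np.outer(ladder, lane))

    sample_ids = annotations.sample_ids
    counts = pd.DataFrame(
        np.vstack([endo_counts, pos_counts, neg_counts]),
        index=pd.Index(endo_ids + pos_ids + neg_ids, name="probe_id"),
        columns=sample_ids,
        dtype=np.int64,
    )
    probe_class = pd.Series(
        ["endogenous"] * len(endo_ids)
        + ["positive"] * len(pos_ids)
        + ["negative"] * len(neg_ids),
        index=counts.index,
    )
    return RawCounts(counts=counts, probe_class=probe_class)


def simulate_cohort(
    spec: CohortSpec, effects: Sequence[EffectSpec] = ()
) -> tuple[SampleAnnotations, RawCounts]:
    """Convenience wrapper: covariates and counts in one call."""
    ann = generate_cohort(spec)
    return ann, generate_counts(ann, spec, effects)


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """A copy of ``spec`` with a different seed (for replicate loops)."""
    return replace(spec, seed=int(seed))
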