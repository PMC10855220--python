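"""OLS / robust linear / robust logistic fits, routing, and the two-stage scan."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from evpmircomp import (
    CohortSpec,
    DegenerateInputError,
    ModelSpec,
    SeparationError,
    composition_mirna_scan,
    fit_ols,
    fit_robust_lm,
    fit_robust_logistic,
    normalize_positive_controls,
    posthoc_factor_scan,
    route_mirnas,
    simulate_cohort,
    summarize_composition,
)
from evpmircomp.composition import DetectionMatrix
from evpmircomp.nanostring_io import NormalizedCounts, SampleAnnotations


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------


def test_ols_exact_fit():
    x = np.arange(10.0)
    df = pd.DataFrame({"y": 2 * x + 1, "x": x})
    r = fit_ols(ModelSpec("y", "x"), df)
    assert r.estimate == pytest.approx(2.0, abs=1e-10)
    assert r.ci_high - r.ci_low == pytest.approx(0.0, abs=1e-8)


def test_ols_binary_predictor_equals_mean_difference():
    df = pd.DataFrame(
        {
            "y": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0],
            "g": pd.Categorical(["a"] * 3 + ["b"] * 3),
        }
    )
    r = fit_ols(ModelSpec("y", "g"), df)
    assert r.estimate == pytest.approx(6.0, abs=1e-12)


def test_ols_null_type_one_error_calibrated():
    """Independent predictor: rejection rate at alpha=0.05 within [0.03, 0.07]."""
    rng = np.random.default_rng(12)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        df = pd.DataFrame({"y": rng.normal(size=50), "x": rng.normal(size=50)})
        rejections += fit_ols(ModelSpec("y", "x"), df).p < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_rank_deficient_design_reports_column():
    df = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [1.0, 2, 3, 4], "z": [2.0, 4, 6, 8]})
    with pytest.raises(DegenerateInputError, match="z"):
        fit_ols(ModelSpec("y", "x", covariates=("z",)), df)


def test_huber_equals_ols_on_clean_data():
    rng = np.random.default_rng(1)
    x = rng.normal(size=60)
    # symmetric two-point noise: every residual sits well inside c * MAD-scale,
    # so all Huber weights are 1 and the M-estimate coincides with OLS
    y = 1.5 * x + 0.5 + 0.01 * rng.choice([-1.0, 1.0], size=60)
    df = pd.DataFrame({"y": y, "x": x})
    ols = fit_ols(ModelSpec("y", "x"), df)
    rob = fit_robust_lm(ModelSpec("y", "x"), df)
    assert rob.estimate == pytest.approx(ols.estimate, abs=1e-6)


def test_huber_resists_gross_outlier():
    x = np.arange(1.0, 21.0)
    y = x.copy()
    y[-1] = 200.0
    df = pd.DataFrame({"y": y, "x": x})
    ols = fit_ols(ModelSpec("y", "x"), df)
    rob = fit_robust_lm(ModelSpec("y", "x"), df)
    assert abs(rob.estimate - 1.0) < abs(ols.estimate - 1.0)
    assert rob.estimate == pytest.approx(1.0, abs=0.05)


def test_huber_bounded_influence_vs_ols_divergence():
    x = np.arange(1.0, 21.0)
    slopes_rob, slopes_ols = [], []
    for outlier in (1e2, 1e5):
        y = x.copy()
        y[-1] = outlier
        df = pd.DataFrame({"y": y, "x": x})
        slopes_rob.append(fit_robust_lm(ModelSpec("y", "x"), df).estimate)
        slopes_ols.append(fit_ols(ModelSpec("y", "x"), df).estimate)
    assert abs(slopes_rob[1] - slopes_rob[0]) < 0.01  # bounded
    assert slopes_ols[1] > 10 * slopes_ols[0]  # diverges


def test_duplicated_rows_leave_estimate_unchanged():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"y": rng.normal(size=30), "x": rng.normal(size=30)})
    dup = pd.concat([df, df], ignore_index=True)
    r1 = fit_robust_lm(ModelSpec("y", "x"), df)
    r2 = fit_robust_lm(ModelSpec("y", "x"), dup)
    assert r2.estimate == pytest.approx(r1.estimate, abs=1e-6)


def test_reference_flip_negates_estimate_and_swaps_ci():
    rng = np.random.default_rng(3)
    g = rng.choice(["a", "b"], size=40)
    y = rng.normal(size=40) + (g == "b")
    df1 = pd.DataFrame({"y": y, "g": pd.Categorical(g, categories=["a", "b"])})
    df2 = pd.DataFrame({"y": y, "g": pd.Categorical(g, categories=["b", "a"])})
    r1 = fit_ols(ModelSpec("y", "g"), df1)
    r2 = fit_ols(ModelSpec("y", "g"), df2)
    assert r2.estimate == pytest.approx(-r1.estimate, abs=1e-10)
    assert r2.ci_low == pytest.approx(-r1.ci_high, abs=1e-10)
    assert r2.ci_high == pytest.approx(-r1.ci_low, abs=1e-10)


def test_exclusion_query_drops_rows_and_reports_n():
    df = pd.DataFrame(
        {"y": [1.0, 2, 3, 4, 5], "x": [0.0, 1, 0, 1, 0], "bmi": [17.0, 22, 24, 30, 21]}
    )
    r = fit_ols(ModelSpec("y", "x", exclude="bmi < 18.5"), df)
    assert r.n == 4


# ---------------------------------------------------------------------------
# robust logistic
# ---------------------------------------------------------------------------


def test_robust_logistic_two_by_two_closed_form():
    """Cells (20,10,10,20): log-odds contrast is -ln 4 (OR = 1/4)."""
    y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
    x = pd.Categorical(
        np.r_[["a"] * 30, ["b"] * 30], categories=["a", "b"]
    )
    df = pd.DataFrame({"y": y, "x": x})
    r = fit_robust_logistic(ModelSpec("y", "x"), df)
    assert r.estimate == pytest.approx(-np.log(4.0), abs=1e-8)
    assert r.ci_low < r.estimate < r.ci_high


def test_robust_logistic_agrees_with_ml_on_clean_data():
    """Mid-range probabilities keep all Pearson residuals inside c: the
    bounded-influence score reduces to the ML score."""
    rng = np.random.default_rng(5)
    x = rng.uniform(-1, 1, size=400)
    eta = 0.3 * x  # probabilities in ~[0.43, 0.57]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    df = pd.DataFrame({"y": y.astype(float), "x": x})
    rob = fit_robust_logistic(ModelSpec("y", "x"), df)
    ml = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert rob.estimate == pytest.approx(ml.params[1], abs=1e-4)


def test_robust_logistic_null_estimate_near_zero():
    rng = np.random.default_rng(6)
    x = rng.normal(size=1000)
    y = rng.binomial(1, 0.5, size=1000).astype(float)
    df = pd.DataFrame({"y": y, "x": x})
    r = fit_robust_logistic(ModelSpec("y", "x"), df)
    assert abs(r.estimate) < 0.2
    assert r.ci_low < 0 < r.ci_high


def test_robust_logistic_downweights_outlying_observation():
    """A mislabeled point far in x shifts the robust fit less than ML."""
    rng = np.random.default_rng(8)
    x = rng.uniform(-1, 1, size=150)
    y = (rng.uniform(size=150) < 1 / (1 + np.exp(-2 * x))).astype(float)
    x_out = np.r_[x, 8.0]
    y_out = np.r_[y, 0.0]  # gross outlier: failure at huge x
    clean = pd.DataFrame({"y": y, "x": x})
    dirty = pd.DataFrame({"y": y_out, "x": x_out})
    rob_clean = fit_robust_logistic(ModelSpec("y", "x"), clean).estimate
    rob_dirty = fit_robust_logistic(ModelSpec("y", "x"), dirty).estimate
    ml_clean = sm.Logit(y, sm.add_constant(x)).fit(disp=0).params[1]
    ml_dirty = sm.Logit(y_out, sm.add_constant(x_out)).fit(disp=0).params[1]
    assert abs(rob_dirty - rob_clean) < abs(ml_dirty - ml_clean)


def test_robust_logistic_one_class_outcome_rejected():
    df = pd.DataFrame({"y": [1.0] * 10, "x": np.arange(10.0)})
    with pytest.raises(DegenerateInputError):
        fit_robust_logistic(ModelSpec("y", "x"), df)


def test_robust_logistic_separation_detected():
    df = pd.DataFrame({"y": [0.0] * 10 + [1.0] * 10, "x": np.arange(20.0)})
    with pytest.raises(SeparationError):
        fit_robust_logistic(ModelSpec("y", "x"), df)


def test_plain_ml_fallback_matches_statsmodels():
    rng = np.random.default_rng(9)
    x = rng.normal(size=200)
    y = rng.binomial(1, 1 / (1 + np.exp(-x))).astype(float)
    df = pd.DataFrame({"y": y, "x": x})
    r = fit_robust_logistic(ModelSpec("y", "x"), df, plain_ml=True)
    ml = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert r.estimate == pytest.approx(ml.params[1], abs=1e-8)


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------


def _det_with_rates(rates, n=100):
    det = pd.DataFrame(
        {f"S{j}": [j < round(r * n) for r in rates] for j in range(n)},
        index=[f"p{i}" for i in range(len(rates))],
    )
    return DetectionMatrix(detected=det, thresholds=pd.Series(1.0, index=det.columns))


def test_routing_boundaries():
    det = _det_with_rates([0.19, 0.20, 0.50, 0.60, 0.61, 1.0])
    modes = [r.mode for r in route_mirnas(det)]
    assert modes == ["excluded", "binary", "binary", "binary", "continuous", "continuous"]


def test_routing_rates_are_detected_fractions():
    det = _det_with_rates([0.25, 0.75])
    routing = route_mirnas(det)
    assert routing[0].detection_rate == pytest.approx(0.25)
    assert routing[1].detection_rate == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# two-stage scan
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def scan_inputs():
    spec = CohortSpec(n_samples=54, n_endogenous=60, seed=42)
    ann, raw = simulate_cohort(spec)
    norm = normalize_positive_controls(raw)
    comp, det = summarize_composition(norm)
    return ann, norm, comp, det


def test_scan_skips_constant_mirnas_and_counts_m_correctly(scan_inputs):
    _, norm, comp, det = scan_inputs
    table = composition_mirna_scan("evenness", comp, norm, det)
    assert not table.empty
    ok = table["status"] == "ok"
    m = int(ok.sum())
    # Bonferroni uses the number of fits that ran, not the panel size
    np.testing.assert_allclose(
        table.loc[ok, "p_bonferroni"], np.minimum(1.0, table.loc[ok, "p"] * m)
    )
    assert table.loc[~ok, "p_bonferroni"].isna().all()


def test_scan_flags_planted_signal(scan_inputs):
    """A miRNA whose log2 counts equal evenness + tiny noise must be flagged."""
    _, norm, comp, det = scan_inputs
    rng = np.random.default_rng(0)
    planted = comp["evenness"].to_numpy() + rng.normal(scale=1e-3, size=len(comp))
    norm2 = NormalizedCounts(
        counts=norm.counts.copy(), norm_factors=norm.norm_factors,
        negatives=norm.negatives, raw_negatives=norm.raw_negatives,
    )
    probe = norm2.counts.index[0]
    norm2.counts.loc[probe] = 2.0 ** (10 * planted)  # log2 = 10 * evenness
    det2 = DetectionMatrix(
        detected=det.detected.copy(), thresholds=det.thresholds,
    )
    det2.detected.loc[probe] = True
    table = composition_mirna_scan("evenness", comp, norm2, det2)
    row = table[table["probe_id"] == probe].iloc[0]
    assert row["mode"] == "continuous"
    assert bool(row["flagged"])


def test_zero_flags_when_all_p_large(scan_inputs):
    _, norm, comp, det = scan_inputs
    rng = np.random.default_rng(1)
    shuffled = comp.copy()
    shuffled["evenness"] = rng.permutation(shuffled["evenness"].to_numpy())
    table = composition_mirna_scan("evenness", shuffled, norm, det)
    # permuting the outcome destroys structure: at most a stray flag survives
    assert int(table["flagged"].sum()) <= 1


def test_posthoc_scans_only_flagged_set(scan_inputs):
    ann, norm, comp, det = scan_inputs
    flagged = list(norm.counts.index[:5])
    table = posthoc_factor_scan(
        "delivery_mode", flagged, (), ann, norm, det
    )
    assert set(table["probe_id"]) == set(flagged)


def test_posthoc_empty_flagged_set_returns_empty(scan_inputs):
    ann, norm, comp, det = scan_inputs
    table = posthoc_factor_scan("delivery_mode", [], (), ann, norm, det)
    assert table.empty
    assert "q" in table.columns


def test_posthoc_single_mirna_q_equals_p(scan_inputs):
    ann, norm, comp, det = scan_inputs
    routing = route_mirnas(det)
    probe = next(r.probe_id for r in routing if r.mode == "continuous")
    table = posthoc_factor_scan("delivery_mode", [probe], (), ann, norm, det, routing)
    row = table.iloc[0]
    assert row["q"] == pytest.approx(row["p"])


def test_posthoc_routes_methods_by_mode(scan_inputs):
    ann, norm, comp, det = scan_inputs
    routing = route_mirnas(det)
    cont = next(r.probe_id for r in routing if r.mode == "continuous")
    binry = next(r.probe_id for r in routing if r.mode == "binary")
    table = posthoc_factor_scan(
        "delivery_mode", [cont, binry], (), ann, norm, det, routing
    )
    by_probe = table.set_index("probe_id")
    assert by_probe.loc[cont, "method"] == "robust_lm"
    ok_binary = by_probe.loc[binry, "status"] == "ok"
    if ok_binary:
        assert by_probe.loc[binry, "method"] == "robust_logistic"


# ---------------------------------------------------------------------------
# parameter recovery through the full model path
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n_samples", [54, 200, 1000])
def test_adjusted_estimate_consistent_as_n_grows(n_samples):
    """Injected -0.703 cesarean log2-total effect is recovered; the error
    shrinks with n."""
    from evpmircomp import EffectSpec
    from evpmircomp.synthetic_data import with_seed

    eff = [EffectSpec("total_counts", "delivery_mode", -0.703)]
    reps = 12 if n_samples <= 200 else 4
    ests = []
    for s in range(reps):
        spec = with_seed(
            CohortSpec(n_samples=n_samples, n_endogenous=150), 7000 + s
        )
        ann, raw = simulate_cohort(spec, eff)
        norm = normalize_positive_controls(raw)
        comp, _ = summarize_composition(norm)
        data = pd.concat([comp, ann.data], axis=1)
        ms = ModelSpec(
            "total_counts_log2", "delivery_mode",
            ("gestational_weight_gain", "parity", "infant_sex", "infant_age_days"),
        )
        ests.append(fit_robust_lm(ms, data).estimate)
    # Monte-Carlo error ~ sd/sqrt(reps*n); generous band that still detects bias
    tol = {54: 0.35, 200: 0.2, 1000: 0.1}[n_samples]
    assert abs(np.mean(ests) - (-0.703)) < tol


def test_robust_lm_matches_mass_rlm_reference(tmp_path):
    """Independent oracle: R's MASS::rlm with the same Huber tuning."""
    import subprocess

    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = 2 * x + 1 + rng.standard_t(df=3, size=40)  # heavy-tailed noise
    df = pd.DataFrame({"y": y, "x": x})
    fixture = tmp_path / "rlm_fixture.csv"
    df.to_csv(fixture, index=False)
    script = (
        f'd <- read.csv("{fixture}"); library(MASS); '
        'f <- rlm(y ~ x, data=d, psi=psi.huber, k=1.345, scale.est="MAD", '
        "maxit=50, acc=1e-8); "
        'cat(sprintf("%.12f", coef(f)[2]))'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    slope_r = float(out.stdout.strip())
    slope_py = fit_robust_lm(ModelSpec("y", "x"), df).estimate
    assert slope_py == pytest.approx(slope_r, abs=1e-4)
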