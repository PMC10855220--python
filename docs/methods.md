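# Methods

`evpmircomp` implements a composition-first analysis of extracellular
vesicle and particle (EVP) miRNA profiles measured on a NanoString
nCounter-style panel (~800 endogenous probes plus synthetic positive and
negative controls), as used in small epidemiological cohorts of maternal
plasma and human milk.  This note records the model, its assumptions, the
defaults that matter, and the design choices made where the design was
genuinely open.

## Normalization

Raw per-probe molecule counts are rescaled lane by lane against the
positive-control probes.  Each lane's positive controls are summarized by
their geometric mean g_s; the lane factor is

    f_s = mean_over_lanes(g) / g_s,

and every endogenous (and negative-control) count in the lane is
multiplied by f_s.  This is the standard CodeCount correction: it is a
per-sample scalar, so within-sample probe ratios and rank order are
untouched, and it is idempotent (renormalizing yields factors of 1).
Whether the positive controls should be summarized by geometric mean or
sum is a genuine open choice; the geometric mean is the default and a
`summary="sum"` dialect is provided.  Normalized counts are kept as reals
(never re-rounded).  Housekeeping- or ligation-control normalization is
deliberately not performed.  A lane whose positive controls are all zero
is an error naming the sample, not a silent drop.

## Detection and composition statistics

A probe is *detected* in a sample when its normalized count strictly
exceeds the sample's background threshold

    threshold_s = mean(neg_s) + 1.5 * SD(neg_s),

with the sample standard deviation (n−1 denominator) over that sample's
negative controls, and the negatives placed on the normalized scale
(multiplied by f_s) so both sides of the comparison share units.
A `dialect="raw"` option thresholds raw counts against raw negatives
instead; with a common multiplier on both sides the two dialects give
identical calls, and both are recorded in run metadata.  The SD
multiplier (1.5) is configurable.

Three per-sample summaries follow:

* **Total counts** — log2 of the sum of normalized counts over *all*
  endogenous probes, detected or not.  Totals are right-skewed, hence
  the log.  The sum deliberately includes sub-threshold probes; detection
  only gates richness and evenness.
* **Richness** s — the number of detected probes.
* **Evenness** — the Pielou statistic over the detected probes,
  E = −Σᵢ pᵢ ln pᵢ / ln s with pᵢ the relative proportion of detected
  probe i.  E ∈ [0, 1]; E = 1 iff all detected probes are equally
  abundant; E is scale-invariant.  For s ≤ 1, ln s vanishes and E is
  reported as missing (not 0 or 1); downstream models drop missing
  outcomes.

## Covariate screening and adjusted models

Candidate covariates are screened against each composition measure with
type-matched nonparametric tests: Spearman correlation (continuous),
two-sided Wilcoxon rank-sum (binary; exact enumeration when both groups
have ≤ 10 observations and no ties, normal approximation with tie
correction otherwise), Kruskal–Wallis (≥ 3 categories).  Pairs with
missing values are dropped listwise per test, maximizing n for each.
Any covariate with p < 0.1 against *any* measure joins the adjustment set
of all subsequent models.  Tie handling in the rank tests follows the
standard corrections; no directional hypotheses are used at screening.

Each factor of interest is then modeled against each measure with both
ordinary least squares and Huber robust linear regression, adjusting for
the selected covariates (minus the factor itself when it was selected).
When weight status enters as a categorical predictor, underweight rows
(BMI < 18.5 kg/m²) are excluded via the model's exclusion rule, because
that category is too sparse in cohorts of this size to estimate a
contrast.  Categorical predictors are reference-coded against their first
level; n is always reported after exclusions and listwise deletion.

**Robust linear regression** is the Huber M-estimator: IRLS with weights
w(u) = min(1, c·ŝ/|u|), tuning constant c = 1.345 (the conventional
95%-efficiency choice), and scale ŝ = MAD(residuals)/0.6745 re-estimated
each iteration; convergence when coefficients change by < 1e-8, at most
50 iterations.  On outlier-free data (all residuals within c·ŝ) it
coincides with OLS; a single gross outlier moves the estimate by a
bounded amount where OLS diverges.

**Inference for robust fits** uses the asymptotic robust covariance with
a t reference distribution on n − p degrees of freedom for p-values and
95% CIs.  The normal reference is anti-conservative in the far tails at
pilot-cohort sizes (n ≈ 54) — exactly the tail that Bonferroni-gated
scans probe — and the t reference restores calibration there; this is
also what mainstream robust-regression summaries report.

## Detection-rate routing and the two-stage per-miRNA scan

Each probe is routed by its detection rate r (detected samples / all
samples): r < 0.20 → excluded (too rare to model), 0.20 ≤ r ≤ 0.60 →
binary detect/non-detect, r > 0.60 → continuous log2 counts (boundaries
inclusive for binary).  Continuous-mode outcomes use log2(count + 1); the
pseudocount (configurable) is needed because an individual probe can be
zero in some samples even at a >60% detection rate.

*Stage 1* regresses richness or evenness on each routed miRNA with robust
linear regression and flags probes at Bonferroni-adjusted p < 0.05, where
the Bonferroni denominator is the number of fits that actually ran
(degenerate probes — constant predictors, failed fits — are recorded and
excluded from the multiplicity count).

*Stage 2* takes a factor associated with that measure and fits adjusted
per-miRNA models of each flagged probe on the factor: robust linear for
continuous-mode probes, robust logistic for binary-mode probes.  Storey
q-values are computed across the scan's successful fits; Q < 0.05 is the
significance rule.  The stage-1 gate is strict: stage 2 never tests a
probe outside the flagged set.

**Robust logistic regression** is a bounded-influence quasi-likelihood
(Cantoni–Ronchetti) estimator: the ML score contributions are replaced by
Huber-ψ-truncated Pearson residuals (c = 1.345) with the
Fisher-consistency correction a_i = E[ψ_c(r_i)] subtracted, solved from
the ML start; the covariance is the sandwich M⁻¹QM⁻ᵀ with M obtained by
numerical differentiation of the estimating function.  On data whose
Pearson residuals all lie within c the corrected score reduces to the ML
score, and on saturated designs the estimator coincides with ML exactly.
Complete or quasi-complete separation (a pure covariate class) is
detected from the ML solution (non-convergence or |log-odds| > 15) and
reported as an error rather than a spurious fit; a plain-ML fallback with
sandwich standard errors is available behind `plain_ml=True`.

## Multiple testing

Bonferroni (min(1, p·m)), Benjamini–Hochberg step-up, and Storey
q-values.  The q-value construction estimates the null proportion
π̂0(λ) = #{p > λ}/(m(1−λ)) over λ ∈ {0.05, …, 0.95}, smooths it with a
cubic fit evaluated at the largest λ, and clamps to (0, 1]; sorted
q-values are q₍ᵢ₎ = min_{j≥i} π̂0·m·p₍ⱼ₎/j.  With π̂0 = 1 this reduces to
BH bit-for-bit (both share one step-up routine).  For scans below 100
tests — the regime of the pipeline's 55–77-probe post hoc scans — the
histogram estimate of π̂0 is unstable, so π̂0 is fixed at 1
(BH-equivalent, conservative); the cutoff and the λ-grid are recorded in
the result object.

## Enrichment

Significant miRNAs are mapped to high-confidence target genes through a
user-supplied miRNA → gene TSV (ids normalized across hsa-miR/hsa-mir
capitalization variants), unioned, and tested per pathway (GMT file) with
the upper-tail hypergeometric probability P[X ≥ k] for an overlap of k
out of n target genes drawn from a universe of N containing K pathway
members, BH-adjusted across pathways (significance at adjusted p < 0.05).
The universe defaults to all genes in the target map but can be supplied
explicitly; since the choice materially affects p, it is always recorded
in run metadata.  Everything is file-based — no web queries — so runs are
reproducible.

## Synthetic cohorts

The generator emulates the measurement process so every downstream stage
is testable without external data:

* **Covariates** drawn from the cohort's published marginals: maternal
  age N(32.6, 4.0²) y; weight status categorical (5.6% under / 72.2%
  normal / 22.2% over) with BMI drawn from the matching truncated
  N(23.9, 4.9²) band so the continuous and categorical views agree row by
  row; gestational weight gain N(34.8, 18.9²) lbs; gestational age at
  delivery N(39.2, 1.5²) wk and at blood collection N(28.8, 2.8²) wk;
  infant age at milk collection N(42.7, 5.6²) days; cesarean proportion
  0.259; male proportion 0.444; afternoon collection 0.5.  The parity
  split is not published; the default is 50/50 primiparous/multiparous.
  Covariates are sampled independently (only marginals are known).
* **Counts**: endogenous probes are negative binomial with probe-specific
  means spanning > 3 orders of magnitude — a `frac_low_abundance`
  fraction (default 0.6) sits near or below background (log-uniform on
  [0.02, 1.2] × background), the rest log-uniform up to 3000 × background
  — and per-probe dispersions uniform on [0.2, 1.0], reproducing the
  zero-inflation and right skew of real panels.  Negative controls are
  Poisson around `background_mean` (default 10) times the lane factor;
  positive controls follow a fixed 6-level, 4-fold titration ladder times
  the lane factor (exact concentrations are irrelevant because
  normalization uses ratios only).
* **Lane factors** are log-normal (σ = 0.25) and multiply every probe in
  a lane, so normalization has real work to do.
* **Biological spread**: each sample carries a log2-normal abundance
  factor (SD 1.0) on endogenous probes only.  Without it, averaging over
  ~800 probes would make log2 totals far tighter (≈ 0.3 log2 units
  between-sample SD) than the adjusted-model CI widths published for
  cohorts like this (≈ ±0.6 at n = 54); SD 1.0 reproduces that spread and
  the right-skew of raw totals.
* **Effects** are injected multiplicatively before lane scaling:
  2^(e·x) on the targeted probe means, with x the 0/1 indicator of a
  binary covariate or the mean-centered value of a continuous one.  A
  `total_counts` effect multiplies every endogenous probe, so the
  downstream log2-total contrast recovers e; a `mirna_subset` effect
  perturbs only the listed probes.

Everything is deterministic under the spec's seed, with separate streams
for covariates, probe parameters, and count noise, so the probe
configuration does not change when only the covariate draw matters.

What the generator does *not* emulate: EVP biology (vesicle counts,
cargo loading), cartridge/batch effects, probe cross-hybridization,
miRNA sequence content, or covariate correlation structure (unless a
user supplies non-default marginals).  Passing tests therefore
demonstrate that the statistical machinery recovers known signals under
a faithful measurement model — not that any particular biological claim
holds in real cohorts.

## Validation experiments and problem sizes

The shipped checks (tests and `scripts/acceptance.py`) use these sizes,
chosen to keep Monte-Carlo error well below the decision margins:

* Formula checks (evenness, detection threshold) on hand-computable
  vectors; agreement to 1e-6.
* Oracle equivalences: exact rank-sum vs enumeration over all group
  assignments (n ≤ 12); hypergeometric tails vs brute-force enumeration
  (N ≤ 13) and vs one-sided Fisher tests; Storey q (π̂0 = 1) vs BH
  (bit-identical); Huber vs OLS on outlier-free data (≤ 1e-6).
* Parameter recovery: 200 simulated cohorts at n = 54 with a −0.703 log2
  cesarean effect on totals and a 150-probe panel; the adjusted robust
  estimate must average within ±0.1 of the truth with ≥ 90% CI coverage.
* False-discovery control: 500 null cohorts at n = 54, scanning 77
  modelable probes per cohort; the mean false-discovery proportion of
  Q < 0.05 calls must stay within 0.05 (+0.03 Monte-Carlo allowance).
  The per-sample biological factor makes probes positively dependent,
  the hard case for FDR procedures.

## Known limitations

* The q-value π̂0 smoother is a least-squares cubic over the λ-grid, not
  a spline with knot-level agreement to any particular reference
  implementation; for the pipeline's own small scans the conservative
  π̂0 = 1 fallback applies anyway.
* Robust-logistic inference is asymptotic (sandwich + t reference);
  at very small n with extreme class imbalance its CIs are approximate.
* Detection thresholds assume the negative controls share the lane's
  scale; probe-specific background (sequence-dependent
  cross-hybridization) is not modeled.
* The screening rule is a marginal p-value filter, as in standard
  epidemiological practice — it is not a causal (DAG-based) confounder
  selection.
* Time-of-day covariates are modeled as binary morning/afternoon
  categories, not continuous clock time.
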