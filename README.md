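# evpmircomp

Composition analysis of extracellular vesicle and particle (EVP) miRNA
profiles from NanoString nCounter-style count data, for epidemiological
studies that ask which maternal, pregnancy, or sample-collection factors
shape the miRNA cargo of biofluids such as prenatal plasma and human
milk.

Pilot-sized cohorts (n ≈ 50) cannot support 800 per-miRNA tests, so the
pipeline works composition-first: counts are normalized to each lane's
positive controls, probes are called *detected* when they exceed the
sample's negative-control background (mean + 1.5 SD), and each sample is
reduced to three summary measures —

* **total counts**: log₂ Σᵢ normalized countᵢ over all endogenous probes,
* **richness** *s*: the number of detected probes,
* **evenness**: the Pielou statistic −Σᵢ pᵢ ln pᵢ / ln s over detected
  probes (1 = all detected miRNAs in equal proportion, undefined for
  s ≤ 1).

Candidate covariates are screened against these measures
(Spearman / Wilcoxon rank-sum / Kruskal–Wallis; any p < 0.1 joins the
adjustment set), and each factor of interest is modeled with OLS and
Huber robust linear regression (c = 1.345, MAD scale).  Factors
associated with richness or evenness trigger a two-stage per-miRNA scan:
stage 1 flags the measure-associated probes (Bonferroni p < 0.05, probes
routed by detection rate — 20–60 % → binary detect/non-detect, > 60 % →
continuous log₂ counts, < 20 % → excluded); stage 2 fits adjusted
per-miRNA models of each flagged probe on the factor (robust linear, or
bounded-influence robust logistic for binary probes) with Storey
q-values at Q < 0.05.  Significant miRNAs feed a file-based target-gene
union and an exact hypergeometric pathway over-representation test
(BH-adjusted).  A synthetic cohort generator with known injected
log₂-scale effects makes the whole chain testable end to end.

## Worked example

Simulate a 54-sample milk-like cohort with a known −0.703 log₂ cesarean
effect on total counts, run every stage, and report:

```python
from evpmircomp import RunConfig, run_pipeline, reproduce_report

cfg = RunConfig.from_mapping({
    "out_dir": "runs/demo",
    "sample_type": "milk",
    "seed": 11,
    "predictors": ["delivery_mode", "parity", "infant_age_days"],
    "simulate": {
        "n_samples": 54,
        "effects": [{"target": "total_counts",
                     "covariate": "delivery_mode",
                     "log2_effect": -0.703}],
    },
})
print(reproduce_report(run_pipeline(cfg)))
```

Output (abridged):

```
evpmircomp run report (milk, n=54)
============================================================

Composition summary
----------------------------------------
  log2 total counts: median 20.35 (IQR 19.29-20.90)
  richness: median 308 (range 201-384)
  evenness: median 0.797 (0 samples undefined)
  detection routing: continuous=285, binary=74, excluded=439

Adjusted associations (per factor x measure)
----------------------------------------
   total_counts_log2 ~ delivery_mode  [      ols] est -0.595 (95% CI -1.258, +0.067) p=0.0771 n=54
   total_counts_log2 ~ delivery_mode  [robust_lm] est -0.562 (95% CI -1.260, +0.136) p=0.112 n=54
            richness ~ delivery_mode  [robust_lm] est -25.083 (95% CI -49.303, -0.863) p=0.0427 n=54
   ...

Post hoc per-miRNA scan
----------------------------------------
  279 flagged miRNAs tested; 17 significant at Q < 0.05
    hsa-miR-sim-0013 [continuous] est -1.020 p=0.011 q=0.0495
    ...
```

Reading it: this one draw's adjusted delivery-mode estimate on log₂
totals (−0.56 to −0.60 depending on estimator) sits inside its CI around
the injected −0.703 — a single n = 54 cohort has wide intervals, which
is exactly why the replicate experiments below average over 200 draws.
The injected total-counts effect also depresses richness, so the
two-stage scan fires and finds individual cesarean-lower probes.

The same stages are exposed as a CLI for shell use:

```bash
evpmircomp run --config config.yaml
evpmircomp simulate --n-samples 54 --seed 1 \
    --effect total_counts:delivery_mode:-0.703 \
    --out-counts counts.tsv --out-annotations ann.csv
evpmircomp normalize --counts counts.tsv --out normalized.tsv
evpmircomp composition --counts counts.tsv --out composition.tsv
evpmircomp enrich --mirnas sig.txt --targets map.tsv --gmt pathways.gmt --out enrichment.tsv
evpmircomp report runs/demo
```

Readers and writers cover TSV count matrices
(`probe_id, probe_class, <samples…>`), NanoString RCC lane-file
directories, annotation CSVs with typed covariate schemas, GMT gene
sets, and miRNA→gene target maps.

## Layout

```
src/evpmircomp/
  synthetic_data.py    cohort + count generator with injected effects
  nanostring_io.py     TSV/RCC readers, annotations, normalization, QC
  composition.py       detection calls, totals, richness, evenness
  screening.py         bivariate screens, p<0.1 covariate selection
  association.py       OLS / Huber / robust logistic, routing, 2-stage scan
  multiple_testing.py  Bonferroni, BH, Storey q-values
  enrichment.py        GMT/target-map parsing, hypergeometric ORA
  pipeline.py          YAML-config orchestration + run reports
  cli.py               `evpmircomp` command group
docs/methods.md        model, defaults, and design decisions
```
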