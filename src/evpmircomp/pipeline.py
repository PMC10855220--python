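"""End-to-end orchestration: simulate/load -> normalize -> composition ->
screen -> adjusted models -> two-stage post hoc scan -> enrichment.

A single YAML config drives the run; every stage writes its table into the
run directory, and ``run_metadata.json`` records versions, seeds,
thresholds and dialect choices so a run is reproducible from the config
alone.  The reporter (:func:`reproduce_report`) only re-reads those
tables; it never recomputes statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    ModelSpec,
    composition_mirna_scan,
    fit_ols,
    fit_robust_lm,
    posthoc_factor_scan,
    results_table,
    route_mirnas,
    routing_table,
)
from .composition import summarize_composition
from .enrichment import enrichment_table, ora_test, read_gmt, read_target_map, union_targets
from .errors import ConfigurationError, EvpMirCompError
from .nanostring_io import (
    normalize_positive_controls,
    read_annotations,
    read_count_table,
    write_annotations,
    write_count_table,
    write_normalized,
)
from .screening import (
    DEFAULT_CANDIDATES,
    MEASURES,
    screen_all,
    screening_table,
    select_covariates,
)
from .synthetic_data import CohortSpec, EffectSpec, simulate_cohort

log = logging.getLogger("evpmircomp")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``counts``/``annotations`` paths or a ``simulate`` block must be
    given.  Thresholds default to the analysis protocol: detection at
    mean + 1.5 SD of negative controls, covariate screen at p < 0.1,
    stage-1 Bonferroni at 0.05, stage-2 FDR at Q < 0.05.
    """

    out_dir: Path
    sample_type: str = "milk"
    counts: Path | None = None
    annotations: Path | None = None
    simulate: dict | None = None
    candidate_covariates: list[str] | None = None
    predictors: list[str] | None = None
    detection_multiplier: float = 1.5
    detection_dialect: str = "normalized"
    screen_alpha: float = 0.1
    bonferroni_alpha: float = 0.05
    q_threshold: float = 0.05
    posthoc: dict | None = None  # {"factor": ..., "measure": ...} or auto
    enrichment: dict | None = None  # {"targets": path, "gmt": path, "universe": path?}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_type not in ("plasma", "milk"):
            raise ConfigurationError(f"sample_type must be plasma/milk, got {self.sample_type!r}")
        if self.simulate is None and (self.counts is None or self.annotations is None):
            raise ConfigurationError(
                "config needs either counts+annotations paths or a simulate block"
            )
        for name in ("screen_alpha", "bonferroni_alpha", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.detection_multiplier <= 0:
            raise ConfigurationError("detection_multiplier must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw, base=Path(path).parent)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any], base: Path | None = None) -> "RunConfig":
        raw = dict(raw)
        if "out_dir" not in raw:
            raise ConfigurationError("config needs out_dir")

        def _p(key: str) -> Path | None:
            v = raw.get(key)
            if v is None:
                return None
            p = Path(v)
            return p if p.is_absolute() or base is None else base / p

        return cls(
            out_dir=Path(raw["out_dir"]),
            sample_type=raw.get("sample_type", "milk"),
            counts=_p("counts"),
            annotations=_p("annotations"),
            simulate=raw.get("simulate"),
            candidate_covariates=raw.get("candidate_covariates"),
            predictors=raw.get("predictors"),
            detection_multiplier=float(raw.get("detection_multiplier", 1.5)),
            detection_dialect=raw.get("detection_dialect", "normalized"),
            screen_alpha=float(raw.get("screen_alpha", 0.1)),
            bonferroni_alpha=float(raw.get("bonferroni_alpha", 0.05)),
            q_threshold=float(raw.get("q_threshold", 0.05)),
            posthoc=raw.get("posthoc"),
            enrichment=raw.get("enrichment"),
            seed=int(raw.get("seed", 0)),
        )


def _spec_from_simulate_block(block: dict, seed: int) -> tuple[CohortSpec, list[EffectSpec]]:
    block = dict(block)
    effects_raw = block.pop("effects", []) or []
    block.setdefault("seed", seed)
    valid = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulate keys: {sorted(unknown)}")
    spec = CohortSpec(**block)
    effects = [
        EffectSpec(
            target=e["target"],
            covariate=e["covariate"],
            log2_effect=float(e["log2_effect"]),
            affected_probes=tuple(e.get("affected_probes", ())),
        )
        for e in effects_raw
    ]
    return spec, effects


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage; returns the run directory.

    Any stage failure is re-raised with the stage name; tables written by
    earlier stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    metadata: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "sample_type": config.sample_type,
        "thresholds": {
            "detection_multiplier": config.detection_multiplier,
            "screen_alpha": config.screen_alpha,
            "bonferroni_alpha": config.bonferroni_alpha,
            "q_threshold": config.q_threshold,
        },
        "detection_dialect": config.detection_dialect,
        "stages": [],
    }
    try:
        # ---------------- simulate or load ----------------
        if config.simulate is not None:
            stage = "simulate"
            spec, effects = _spec_from_simulate_block(config.simulate, config.seed)
            ann, raw = simulate_cohort(spec, effects)
            write_count_table(raw, out / "counts.tsv")
            write_annotations(ann, out / "annotations.csv")
            metadata["simulate"] = {
                "n_samples": spec.n_samples,
                "n_endogenous": spec.n_endogenous,
                "seed": spec.seed,
                "effects": [dataclasses.asdict(e) for e in effects],
            }
        else:
            stage = "load"
            raw = read_count_table(config.counts)
            ann = read_annotations(config.annotations, count_sample_ids=raw.sample_ids)
        metadata["n_samples"] = len(raw.sample_ids)
        metadata["stages"].append(stage)

        # ---------------- normalize ----------------
        stage = "normalize"
        norm = normalize_positive_controls(raw)
        write_normalized(norm, out / "normalized.tsv")
        metadata["stages"].append(stage)

        # ---------------- composition ----------------
        stage = "composition"
        comp, det = summarize_composition(
            norm,
            sd_multiplier=config.detection_multiplier,
            dialect=config.detection_dialect,
        )
        comp.to_csv(out / "composition.tsv", sep="\t")
        routing = route_mirnas(det)
        routing_table(routing).to_csv(out / "routing.tsv", sep="\t", index=False)
        metadata["stages"].append(stage)

        # ---------------- screen ----------------
        stage = "screen"
        candidates = config.candidate_covariates or [
            c for c in DEFAULT_CANDIDATES[config.sample_type] if c in ann.data.columns
        ]
        screen_results = screen_all(comp, ann, candidates)
        screening_table(screen_results).to_csv(
            out / "screening.tsv", sep="\t", index=False
        )
        selected = select_covariates(screen_results, alpha=config.screen_alpha)
        metadata["selected_covariates"] = selected
        metadata["stages"].append(stage)

        # ---------------- adjusted models ----------------
        stage = "associate"
        predictors = config.predictors or candidates
        data = pd.concat([comp, ann.data], axis=1)
        assoc = []
        for predictor in predictors:
            adj = tuple(c for c in selected if c != predictor)
            exclude = (
                "pre_pregnancy_bmi < 18.5"
                if predictor == "weight_status" and "pre_pregnancy_bmi" in data.columns
                else None
            )
            for measure in MEASURES:
                spec_m = ModelSpec(
                    outcome=measure, predictor=predictor, covariates=adj, exclude=exclude
                )
                for fitter in (fit_ols, fit_robust_lm):
                    try:
                        assoc.append(fitter(spec_m, data))
                    except EvpMirCompError as exc:
                        log.warning("associate: %s ~ %s failed: %s", measure, predictor, exc)
        assoc_table = results_table(assoc)
        assoc_table.to_csv(out / "associations.tsv", sep="\t", index=False)
        metadata["stages"].append(stage)

        # ---------------- post hoc two-stage scan ----------------
        stage = "posthoc"
        posthoc_pairs = _posthoc_pairs(config, assoc_table)
        scans = []
        for factor, measure in posthoc_pairs:
            scan1 = composition_mirna_scan(
                measure, comp, norm, det, routing, alpha=config.bonferroni_alpha
            )
            scan1.to_csv(out / f"scan_{measure}.tsv", sep="\t", index=False)
            flagged = scan1.loc[scan1["flagged"] == True, "probe_id"].tolist()  # noqa: E712
            adj = tuple(c for c in selected if c != factor)
            scan2 = posthoc_factor_scan(
                factor, flagged, adj, ann, norm, det, routing,
                q_threshold=config.q_threshold,
            )
            scan2.insert(0, "factor", factor)
            scan2.insert(1, "measure", measure)
            scans.append(scan2)
        posthoc_table = (
            pd.concat(scans, ignore_index=True)
            if scans
            else pd.DataFrame(
                columns=["factor", "measure", "probe_id", "mode", "estimate",
                         "ci_low", "ci_high", "p", "n", "method", "status",
                         "q", "significant"]
            )
        )
        posthoc_table.to_csv(out / "posthoc.tsv", sep="\t", index=False)
        metadata["posthoc_pairs"] = [list(p) for p in posthoc_pairs]
        metadata["stages"].append(stage)

        # ---------------- enrichment ----------------
        if config.enrichment:
            stage = "enrich"
            sig = posthoc_table.loc[
                posthoc_table["significant"] == True, "probe_id"  # noqa: E712
            ].unique().tolist()
            if sig:
                tmap = read_target_map(config.enrichment["targets"])
                collection = read_gmt(config.enrichment["gmt"])
                targets, missing = union_targets(sig, tmap)
                if config.enrichment.get("universe"):
                    universe = frozenset(
                        g.strip().upper()
                        for g in Path(config.enrichment["universe"]).read_text().split()
                        if g.strip()
                    )
                else:
                    universe = tmap.genes()
                results, dropped = ora_test(targets, collection, universe)
                enrichment_table(results).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False
                )
                metadata["enrichment"] = {
                    "n_significant_mirnas": len(sig),
                    "n_target_genes": len(targets),
                    "mirnas_missing_from_map": missing,
                    "universe_size": len(universe),
                    "targets_outside_universe": dropped,
                    "universe_source": (
                        "file" if config.enrichment.get("universe") else "target_map"
                    ),
                }
            else:
                metadata["enrichment"] = {"n_significant_mirnas": 0}
            metadata["stages"].append(stage)
    except EvpMirCompError as exc:
        (out / "run_metadata.json").write_text(
            json.dumps({**metadata, "failed_stage": stage, "error": str(exc)}, indent=2)
        )
        raise EvpMirCompError(f"stage {stage!r} failed: {exc}") from exc

    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
    return out


def _posthoc_pairs(config: RunConfig, assoc: pd.DataFrame) -> list[tuple[str, str]]:
    """Which (factor, measure) pairs get a two-stage scan.

    Explicit via the config's posthoc block, otherwise every robust-fit
    association of a factor with richness or evenness at p < 0.05.
    """
    if config.posthoc:
        return [(config.posthoc["factor"], config.posthoc["measure"])]
    if assoc.empty:
        return []
    hits = assoc[
        (assoc["method"] == "robust_lm")
        & assoc["outcome"].isin(["richness", "evenness"])
        & (assoc["p"] < 0.05)
    ]
    return [(r.predictor, r.outcome) for r in hits.itertuples()]


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def reproduce_report(run_dir: str | Path) -> str:
    """Human-readable summary assembled from a completed run's tables."""
    run_dir = Path(run_dir)
    needed = ["composition.tsv", "associations.tsv", "run_metadata.json"]
    absent = [f for f in needed if not (run_dir / f).exists()]
    if absent:
        raise EvpMirCompError(f"incomplete run directory; missing {absent}")
    meta = json.loads((run_dir / "run_metadata.json").read_text())
    comp = pd.read_csv(run_dir / "composition.tsv", sep="\t", index_col=0)
    assoc = pd.read_csv(run_dir / "associations.tsv", sep="\t")
    lines = [
        f"evpmircomp run report ({meta.get('sample_type', '?')}, "
        f"n={meta.get('n_samples', '?')})",
        "=" * 60,
        "",
        "Composition summary",
        "-" * 40,
        f"  log2 total counts: median {comp['total_counts_log2'].median():.2f} "
        f"(IQR {comp['total_counts_log2'].quantile(0.25):.2f}-"
        f"{comp['total_counts_log2'].quantile(0.75):.2f})",
        f"  richness: median {comp['richness'].median():.0f} "
        f"(range {comp['richness'].min():.0f}-{comp['richness'].max():.0f})",
        f"  evenness: median {comp['evenness'].median():.3f} "
        f"({comp['evenness'].isna().sum()} samples undefined)",
        "",
        "Adjusted associations (per factor x measure)",
        "-" * 40,
    ]
    if (run_dir / "routing.tsv").exists():
        routing = pd.read_csv(run_dir / "routing.tsv", sep="\t")
        counts = routing["mode"].value_counts()
        lines.insert(
            8,
            "  detection routing: "
            + ", ".join(f"{m}={int(counts.get(m, 0))}" for m in
                        ("continuous", "binary", "excluded")),
        )
    for row in assoc.itertuples():
        lines.append(
            f"  {row.outcome:>18} ~ {row.predictor:<24} [{row.method:>9}] "
            f"est {row.estimate:+.3f} (95% CI {row.ci_low:+.3f}, {row.ci_high:+.3f}) "
            f"p={row.p:.3g} n={row.n}"
        )
    posthoc_path = run_dir / "posthoc.tsv"
    lines += ["", "Post hoc per-miRNA scan", "-" * 40]
    if posthoc_path.exists():
        ph = pd.read_csv(posthoc_path, sep="\t")
        if ph.empty:
            lines.append("  no stage-1 flagged miRNAs")
        else:
            n_sig = int((ph["significant"] == True).sum())  # noqa: E712
            lines.append(
                f"  {len(ph)} flagged miRNAs tested; {n_sig} significant at "
                f"Q < {meta['thresholds']['q_threshold']}"
            )
            for row in ph[ph["significant"] == True].itertuples():  # noqa: E712
                lines.append(
                    f"    {row.probe_id} [{row.mode}] est {row.estimate:+.3f} "
                    f"p={row.p:.3g} q={row.q:.3g}"
                )
    else:
        lines.append("  (stage not run)")
    enr_path = run_dir / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        lines += ["", "Pathway over-representation", "-" * 40]
        top = enr.head(10)
        for row in top.itertuples():
            lines.append(
                f"  {row.pathway}: k={row.overlap}/{row.set_size} "
                f"p={row.p:.3g} p_adj={row.p_adjusted:.3g}"
            )
    return "\n".join(lines) + "\n"
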