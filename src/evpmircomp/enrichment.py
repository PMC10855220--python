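"""Target-gene unions and exact pathway over-representation tests.

Significant miRNAs are mapped to their high-confidence target genes via a
user-supplied miRNA -> gene table, the per-miRNA sets are unioned, and
each pathway gene set (GMT file) is tested for over-representation of the
union with an upper-tail hypergeometric probability P[X >= k] against an
explicit gene universe, BH-adjusted across pathways.  Everything is
file-based; no web services are queried, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, FormatError
from .multiple_testing import bh_adjust


@dataclass
class GeneSetCollection:
    """Named pathway gene sets (symbols uppercased, deduplicated)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"empty gene set {name!r}")


@dataclass
class TargetMap:
    """miRNA id -> target gene set (ids normalized to lowercase hsa-mir)."""

    targets: dict[str, frozenset[str]]
    confidence: str = ""

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.targets.values():
            out |= g
        return frozenset(out)


@dataclass
class EnrichmentResult:
    pathway: str
    overlap: int  # k
    set_size: int  # K (pathway genes in universe)
    target_size: int  # n (targets in universe)
    universe_size: int  # N
    p: float
    p_adjusted: float = float("nan")


def normalize_mirna_id(mirna: str) -> str:
    """Unify capitalization variants like hsa-miR-21-5p / hsa-mir-21-5p."""
    return mirna.strip().lower()


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``name <tab> description <tab> gene...`` per line."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path.name}:{ln}: expected name, description, >=1 gene")
        name = parts[0].strip()
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            raise FormatError(f"{path.name}:{ln}: no genes in set {name!r}")
        if name in sets:
            raise FormatError(f"{path.name}:{ln}: duplicate pathway name {name!r}")
        sets[name] = genes
    return GeneSetCollection(sets=sets, source=source or path.name)


def read_target_map(path: str | Path, confidence: str = "") -> TargetMap:
    """Read a two-column TSV ``mirna_id <tab> gene`` into a TargetMap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna", "gene"], dtype=str)
    if df.isna().any().any():
        raise FormatError(f"{path}: incomplete mirna/gene rows")
    targets: dict[str, set[str]] = {}
    for mirna, gene in zip(df["mirna"], df["gene"]):
        targets.setdefault(normalize_mirna_id(mirna), set()).add(gene.strip().upper())
    return TargetMap(
        targets={k: frozenset(v) for k, v in targets.items()}, confidence=confidence
    )


def union_targets(
    mirnas: list[str], target_map: TargetMap
) -> tuple[frozenset[str], list[str]]:
    """Union of target sets of the listed miRNAs.

    Returns ``(union, missing)`` where ``missing`` lists miRNAs absent
    from the map (warned about, not fatal).
    """
    if not mirnas:
        raise ConfigurationError("empty miRNA list")
    union: set[str] = set()
    missing: list[str] = []
    for m in mirnas:
        key = normalize_mirna_id(m)
        if key in target_map.targets:
            union |= target_map.targets[key]
        else:
            missing.append(m)
    return frozenset(union), missing


def ora_test(
    targets: frozenset[str] | set[str],
    collection: GeneSetCollection,
    universe: frozenset[str] | set[str],
) -> tuple[list[EnrichmentResult], int]:
    """Hypergeometric over-representation of ``targets`` in each pathway.

    The universe must be explicit; target genes outside it are dropped and
    their count returned.  For each pathway the test draws n = |targets in
    universe| genes from N = |universe| of which K are pathway members and
    reports P[X >= k] for the observed overlap k, with BH adjustment
    across pathways; results are sorted by adjusted then raw p.
    """
    universe = frozenset(g.upper() for g in universe)
    if not universe:
        raise ConfigurationError("empty universe")
    targets_in = frozenset(g.upper() for g in targets) & universe
    n_dropped = len(set(g.upper() for g in targets)) - len(targets_in)
    N, n = len(universe), len(targets_in)
    results: list[EnrichmentResult] = []
    for name, genes in collection.sets.items():
        pathway_in = frozenset(g.upper() for g in genes) & universe
        K = len(pathway_in)
        if K == 0:
            raise ConfigurationError(
                f"pathway {name!r} has no genes in the universe"
            )
        k = len(pathway_in & targets_in)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(name, k, K, n, N, p))
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.p_adjusted, r.p, r.pathway))
    return results, n_dropped


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "target_size": r.target_size,
                "universe_size": r.universe_size,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )
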