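"""Consensus miRNA-target calling, renal-gene counting and pathway
over-representation.

A gene is a consensus target of a miRNA when at least ``min_sources`` of
the supplied prediction sources (e.g. three seed-match algorithms) agree.
Renal counts intersect each miRNA's consensus set with a curated list of
kidney-relevant genes and later drive differential shrinkage in the
prognostic model.  Over-representation uses the upper-tail hypergeometric
test with Benjamini-Hochberg control of the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TargetSet",
    "EnrichmentResult",
    "build_consensus",
    "renal_counts",
    "enrich",
    "read_target_table",
    "read_gene_list",
    "read_gmt",
]


@dataclass
class TargetSet:
    """Consensus miRNA→gene map with per-source provenance."""

    consensus: dict[str, set[str]]
    sources: dict[str, dict[str, set[str]]]  # mirna -> source name -> genes
    renal_genes: set[str] = field(default_factory=set)
    renal_count: dict[str, int] = field(default_factory=dict)

    def universe(self) -> set[str]:
        """Union of every gene any source predicts for any miRNA."""
        return {
            g
            for per_source in self.sources.values()
            for genes in per_source.values()
            for g in genes
        }


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int  # overlap
    K: int  # pathway size within universe
    n: int  # query size
    N: int  # universe size
    fold_enrichment: float
    p: float
    q: float
    significant: bool


def read_target_table(path: str | Path) -> tuple[str, dict[str, set[str]]]:
    """Read a flat ``mirna<TAB>gene<TAB>source`` prediction table.

    Returns (source name, mirna -> gene set); the source column must be
    constant within a file.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna", "gene", "source"],
                     dtype=str, comment="#")
    names = df["source"].dropna().unique()
    source = names[0] if len(names) else Path(path).stem
    table: dict[str, set[str]] = {}
    for m, g in zip(df["mirna"], df["gene"]):
        table.setdefault(m, set()).add(g)
    return source, table


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT pathway file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        pathways[parts[0]] = {g for g in parts[2:] if g}
    return pathways


def build_consensus(
    source_tables: Mapping[str, Mapping[str, Sequence[str] | set[str]]],
    min_sources: int = 2,
) -> TargetSet:
    """Consensus = genes predicted for a miRNA by >= ``min_sources`` sources.

    ``source_tables`` maps source name -> (mirna -> genes); gene identifiers
    must already share one namespace.
    """
    if len(source_tables) < min_sources:
        raise ValueError(
            f"need at least min_sources={min_sources} source tables, "
            f"got {len(source_tables)}"
        )
    mirnas = {m for tbl in source_tables.values() for m in tbl}
    sources: dict[str, dict[str, set[str]]] = {}
    consensus: dict[str, set[str]] = {}
    for m in sorted(mirnas):
        per = {name: set(tbl.get(m, ())) for name, tbl in source_tables.items()}
        sources[m] = per
        votes: dict[str, int] = {}
        for genes in per.values():
            for g in genes:
                votes[g] = votes.get(g, 0) + 1
        consensus[m] = {g for g, v in votes.items() if v >= min_sources}
    return TargetSet(consensus=consensus, sources=sources)


def renal_counts(targets: TargetSet, renal_genes: set[str]) -> dict[str, int]:
    """Number of kidney-relevant genes among each miRNA's consensus targets.

    Also stored on the TargetSet (``renal_genes`` / ``renal_count``).
    """
    counts = {m: len(genes & renal_genes) for m, genes in targets.consensus.items()}
    targets.renal_genes = set(renal_genes)
    targets.renal_count = counts
    return counts


def enrich(
    query_genes: set[str],
    pathways: Mapping[str, set[str]],
    universe: set[str],
    fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query in each pathway.

    p = P(X >= k) with X ~ Hypergeom(N, K, n); q = BH adjustment across
    pathways; results sorted by q then decreasing fold enrichment.  Empty
    query gives an empty list.
    """
    if not query_genes:
        return []
    if not query_genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query_genes)
    rows = []
    for name, genes in pathways.items():
        in_universe = genes & universe
        if not in_universe:
            raise ValueError(f"pathway {name!r} has no genes in the universe")
        K = len(in_universe)
        k = len(query_genes & in_universe)
        fold = (k / n) / (K / N)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, fold, min(p, 1.0)))
    _, q, _, _ = multipletests([r[4] for r in rows], method="fdr_bh")
    results = [
        EnrichmentResult(name, k, K, n, N, fold, p, float(qv), bool(qv <= fdr))
        for (name, k, K, fold, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.q, -r.fold_enrichment, r.pathway))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
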