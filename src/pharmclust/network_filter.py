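"""Network-driven pruning of gene modules.

Each module is intersected with the interaction graph: genes must first
have at least one strong edge (combined score >= 0.7 by default) to
another gene of the same module, and the connected components of that
strong subgraph define the module's "biological networks".  Within each
network a gene is kept only if its mean Pearson correlation with the
other members is at least 0.5.  Networks reduced to a single gene are
dropped — a lone gene has no co-expression evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datatypes import ExpressionMatrix, GeneModule, InteractionGraph

__all__ = ["FilterReport", "filter_by_network"]


@dataclass(frozen=True)
class FilterReport:
    module_id: str
    kept_gene_ids: frozenset
    dropped: dict  # gene -> "no_strong_edge" | "low_correlation"
    networks: tuple  # tuple of frozensets: the strong components examined

    def __post_init__(self) -> None:
        overlap = self.kept_gene_ids & set(self.dropped)
        if overlap:
            raise ValueError(f"genes both kept and dropped: {sorted(overlap)[:3]}")


def _strong_subgraph(
    module_genes: frozenset, graph: InteractionGraph, score_min: float
) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(module_genes)
    for pair, score in graph.edges.items():
        if score >= score_min and pair <= module_genes:
            a, b = pair
            g.add_edge(a, b)
    return g


def filter_by_network(
    module: GeneModule,
    graph: InteractionGraph,
    expr: ExpressionMatrix,
    score_min: float = 0.7,
    corr_min: float = 0.5,
    correlation_rule: str = "mean",
) -> FilterReport:
    """Prune a gene module to its connected, co-expressed core.

    ``correlation_rule`` selects how the co-expression criterion is
    evaluated within each strong network: "mean" (default) keeps a gene
    if its mean correlation with the other members is >= corr_min;
    "max" keeps it if any single correlation reaches the threshold.
    Both thresholds are inclusive.
    """
    if not module.gene_ids:
        raise ValueError("empty module")
    missing = [g for g in module.gene_ids if g not in expr.values.index]
    if missing:
        raise KeyError(f"module genes absent from expression matrix: {missing[:5]}")
    if correlation_rule not in ("mean", "max"):
        raise ValueError(f"unknown correlation_rule {correlation_rule!r}")

    strong = _strong_subgraph(module.gene_ids, graph, score_min)
    dropped: dict[str, str] = {}
    networks: list[frozenset] = []
    kept: set[str] = set()

    for comp in nx.connected_components(strong):
        comp = frozenset(comp)
        if len(comp) < 2:
            for g in comp:
                dropped[g] = "no_strong_edge"
            continue
        networks.append(comp)
        members = sorted(comp)
        sub = expr.values.loc[members].to_numpy(dtype=float)
        r = np.corrcoef(sub)
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, np.nan)
        if correlation_rule == "mean":
            stat = np.nanmean(r, axis=1)
        else:
            stat = np.nanmax(r, axis=1)
        for g, s in zip(members, stat):
            if s >= corr_min:
                kept.add(g)
            else:
                dropped[g] = "low_correlation"

    return FilterReport(
        module_id=module.module_id,
        kept_gene_ids=frozenset(kept),
        dropped=dropped,
        networks=tuple(sorted(networks, key=lambda c: sorted(c))),
    )
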