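"""Gene-level network construction and graph / enrichment statistics.

Isoform networks are collapsed to gene networks by merging all isoform nodes
of a gene into one gene node: intra-gene edges become self-loops and are
dropped; parallel inter-gene edges are deduplicated, keeping the minimum
weight and a multiplicity count. Graph summaries, top-decile central nodes
(intersection of betweenness and degree centrality on the largest connected
component), pairwise shared-edge fractions, per-gene tissue rankings and
one-sided hypergeometric enrichment with Benjamini-Hochberg control follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GeneCatalog
from .exceptions import DataError
from .pair_features import canonical_pair


def collapse_to_genes(
    isoform_edges: Iterable[tuple[str, str, float]],
    catalog: GeneCatalog,
    tissue: str = "",
) -> nx.Graph:
    """Merge isoform nodes into gene nodes; see module docstring for rules."""
    graph = nx.Graph(tissue=tissue)
    for a, b, weight in isoform_edges:
        if a not in catalog or b not in catalog:
            missing = a if a not in catalog else b
            raise DataError(f"isoform {missing} has no gene mapping")
        ga, gb = catalog.gene_of(a), catalog.gene_of(b)
        if ga == gb:
            continue  # intra-gene edge collapses to a self-loop
        ga, gb = canonical_pair(ga, gb)
        if graph.has_edge(ga, gb):
            data = graph[ga][gb]
            data["weight"] = min(data["weight"], float(weight))
            data["multiplicity"] += 1
        else:
            graph.add_edge(ga, gb, weight=float(weight), multiplicity=1)
    return graph


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_edges: int
    density: float
    n_components: int
    largest_component_size: int


def summarize(graph: nx.Graph) -> GraphSummary:
    """Node/edge counts, density 2E/(N(N-1)), components, largest component."""
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    components = list(nx.connected_components(graph))
    largest = max((len(c) for c in components), default=0)
    return GraphSummary(
        n_nodes=n,
        n_edges=e,
        density=density,
        n_components=len(components),
        largest_component_size=largest,
    )


def _top_fraction(
    scores: Mapping[str, float],
    secondary: Mapping[str, float],
    fraction: float,
) -> set[str]:
    k = max(1, floor(fraction * len(scores)))
    ordered = sorted(
        scores, key=lambda node: (-scores[node], -secondary[node], node)
    )
    return set(ordered[:k])


def central_nodes(graph: nx.Graph, fraction: float = 0.10) -> set[str]:
    """Nodes in the top decile by BOTH betweenness and degree centrality.

    Computed on the largest connected component only; betweenness is
    unweighted. Ties in one measure break by the other measure (the two are
    intersected anyway), then by node id, so the result is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise DataError("central_nodes requires a nonempty graph")
    largest = max(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)))
    component = graph.subgraph(largest)
    betweenness = nx.betweenness_centrality(component)
    degree = dict(component.degree())
    return _top_fraction(betweenness, degree, fraction) & _top_fraction(
        degree, betweenness, fraction
    )


def _edge_set(graph: nx.Graph) -> set[tuple[str, str]]:
    return {canonical_pair(a, b) for a, b in graph.edges}


def shared_pair_fractions(networks: Mapping[str, nx.Graph]) -> pd.DataFrame:
    """Row-weighted fraction of edges shared between tissue networks.

    Entry (i, j) = |E_i intersect E_j| / |E_i|; asymmetric; diagonal 1.
    """
    if len(networks) < 2:
        raise DataError("need at least two tissue networks")
    tissues = list(networks)
    edge_sets = {t: _edge_set(networks[t]) for t in tissues}
    table = pd.DataFrame(0.0, index=tissues, columns=tissues)
    for ti in tissues:
        for tj in tissues:
            if ti == tj:
                table.loc[ti, tj] = 1.0
            elif edge_sets[ti]:
                table.loc[ti, tj] = len(edge_sets[ti] & edge_sets[tj]) / len(
                    edge_sets[ti]
                )
    return table


def rank_tissues_per_gene(
    networks: Mapping[str, nx.Graph]
) -> dict[str, list[str]]:
    """Tissues ordered per gene by functional interaction count, descending.

    Ties break by tissue name; genes with no edges anywhere are omitted, so
    an absent gene ranks as an empty list.
    """
    counts: dict[str, dict[str, int]] = {}
    for tissue, graph in networks.items():
        for node in graph.nodes:
            deg = graph.degree(node)
            if deg > 0:
                counts.setdefault(node, {})[tissue] = deg
    return {
        gene: sorted(per_tissue, key=lambda t: (-per_tissue[t], t))
        for gene, per_tissue in counts.items()
    }


def enrichment(
    central_genes: Iterable[str],
    term_gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    min_term_size: int = 10,
    max_term_size: int = 1000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment with BH adjustment.

    For a universe of M genes, a term annotating K of them, and a query of n
    central genes of which k fall in the term, p = P(X >= k) for
    X ~ Hypergeometric(M, K, n). Terms outside [min_term_size,
    max_term_size] are excluded; adjusted p <= alpha is flagged significant.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty gene universe")
    query = set(central_genes) & universe
    if not query <= universe:  # pragma: no cover - defensive
        raise DataError("central genes must lie inside the universe")
    big_m = len(universe)
    n = len(query)
    rows = []
    for term in sorted(term_gene_sets):
        term_genes = term_gene_sets[term] & universe
        big_k = len(term_genes)
        if not (min_term_size <= big_k <= max_term_size):
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, big_m, big_k, n))
        rows.append(
            {
                "term": term,
                "term_size": big_k,
                "overlap": k,
                "p_value": min(1.0, p),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "p_value"]
    )
    if len(table):
        table["p_adjusted"] = stats.false_discovery_control(
            table["p_value"].values, method="bh"
        )
        table["significant"] = table["p_adjusted"] <= alpha
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table.set_index("term")
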