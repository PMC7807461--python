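"""Spearman/FDR co-occurrence networks, topology, and keystone ranking.

Two threshold regimes are supported, matching common practice for rumen
community networks:

* core regime: an edge requires |rho| > 0.3 AND BH-adjusted p < 0.05;
* age-specific regime: an edge requires |rho| >= 0.5, no p filtering.

Edge signs (positive/negative correlation) are carried as metadata but
ignored for all topology and betweenness computations.  Isolated taxa are
dropped, so a network's node set is exactly the endpoints of its edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from rumenage.tables import FeatureTable, SampleMetadata, relative_abundance

__all__ = [
    "CorrelationResult",
    "TopologySummary",
    "KeystoneRanking",
    "spearman_matrix",
    "bh_adjust",
    "build_core_network",
    "build_age_specific_network",
    "topology",
    "betweenness_keystones",
    "meta_network",
]


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationResult:
    """All-pairs Spearman correlations with raw and BH-adjusted p-values."""

    taxa: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_samples: int

    def pairs(self):
        """Iterate upper-triangle (taxon_a, taxon_b, rho, q) tuples."""
        for i, a in enumerate(self.taxa):
            for b in self.taxa[i + 1:]:
                yield a, b, float(self.rho.loc[a, b]), float(self.q.loc[a, b])


def spearman_matrix(relabund: pd.DataFrame) -> CorrelationResult:
    """Tie-corrected Spearman rho over taxon pairs with t-approximation p.

    Zero-variance taxa are removed with a warning before correlation; the
    BH adjustment runs over the upper triangle only.
    """
    if relabund.shape[0] < 4:
        raise ValueError("need at least 4 samples for Spearman correlation")
    variances = relabund.var(axis=0)
    constant = variances.index[variances == 0].tolist()
    if constant:
        warnings.warn(f"removing {len(constant)} zero-variance taxa: {constant[:5]}...",
                      stacklevel=2)
        relabund = relabund.drop(columns=constant)
    if relabund.shape[1] < 2:
        raise ValueError("need at least 2 variable taxa")
    taxa = list(relabund.columns)
    rho, p = scipy.stats.spearmanr(relabund.to_numpy())
    if np.isscalar(rho):  # scipy returns scalars for exactly two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(len(taxa), k=1)
    q = np.zeros_like(p)
    q[iu] = bh_adjust(p[iu])
    q = q + q.T
    return CorrelationResult(
        taxa=taxa,
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        q=pd.DataFrame(q, index=taxa, columns=taxa),
        n_samples=relabund.shape[0],
    )


def _assemble(corr: CorrelationResult, edge_rule, node_attrs=None) -> nx.Graph:
    g = nx.Graph()
    for a, b, rho, q in corr.pairs():
        if edge_rule(rho, q):
            g.add_edge(a, b, rho=rho, sign="positive" if rho > 0 else "negative")
    if node_attrs:
        for node in g.nodes:
            g.nodes[node].update(node_attrs.get(node, {}))
    return g


def build_core_network(
    corr: CorrelationResult,
    rho_min: float = 0.3,
    q_max: float = 0.05,
    node_attrs: dict | None = None,
) -> nx.Graph:
    """Core regime: |rho| > rho_min AND adjusted p < q_max."""
    return _assemble(corr, lambda r, q: abs(r) > rho_min and q < q_max, node_attrs)


def build_age_specific_network(
    corr: CorrelationResult,
    rho_min: float = 0.5,
    node_attrs: dict | None = None,
) -> nx.Graph:
    """Age-specific regime: |rho| >= rho_min, no p filtering."""
    return _assemble(corr, lambda r, q: abs(r) >= rho_min, node_attrs)


@dataclass
class TopologySummary:
    """Global graph metrics in the convention of co-occurrence tables.

    ``clustering_coefficient`` is the mean local clustering (nodes of
    degree < 2 contribute 0); global transitivity is co-reported.
    ``average_path_length`` averages over connected unordered pairs and is
    NaN when no such pair exists.
    """

    n_nodes: int
    n_edges: int
    average_path_length: float
    graph_density: float
    clustering_coefficient: float
    average_degree: float
    transitivity: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_path_length": self.average_path_length,
            "graph_density": self.graph_density,
            "clustering_coefficient": self.clustering_coefficient,
            "average_degree": self.average_degree,
            "transitivity": self.transitivity,
        }


def topology(net: nx.Graph) -> TopologySummary:
    """Node/edge counts plus path length, density, clustering, mean degree."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, np.nan, np.nan, np.nan, np.nan, np.nan)
    avg_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else np.nan
    clustering = float(nx.average_clustering(net, count_zeros=True))
    trans = float(nx.transitivity(net))
    total, pairs = 0.0, 0
    for comp in nx.connected_components(net):
        m = len(comp)
        if m < 2:
            continue
        sub = net.subgraph(comp)
        total += sum(
            sum(lengths.values()) for _, lengths in nx.all_pairs_shortest_path_length(sub)
        ) / 2.0
        pairs += m * (m - 1) // 2
    apl = total / pairs if pairs else np.nan
    return TopologySummary(n, e, apl, density, clustering, avg_degree, trans)


@dataclass
class KeystoneRanking:
    """Taxa ranked by unnormalized betweenness centrality (descending)."""

    taxa: list[str]
    scores: list[float]
    k: int


def betweenness_keystones(net: nx.Graph, k: int = 5) -> KeystoneRanking:
    """Top-k taxa by shortest-path betweenness on the sign-ignored graph.

    Ties break deterministically: score descending, then taxon id
    lexicographic.  ``k`` larger than the node count is clipped with a
    warning.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if k > net.number_of_nodes():
        warnings.warn(f"k={k} exceeds node count {net.number_of_nodes()}; clipped",
                      stacklevel=2)
        k = net.number_of_nodes()
    bc = nx.betweenness_centrality(net, normalized=False)
    ranked = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return KeystoneRanking(
        taxa=[t for t, _ in ranked], scores=[float(s) for _, s in ranked], k=k
    )


def meta_network(
    tables: dict[str, FeatureTable],
    metadata: SampleMetadata,
    regime: str = "core",
    rho_min: float | None = None,
    q_max: float = 0.05,
    taxa_per_kingdom: dict[str, set[str]] | None = None,
) -> nx.Graph:
    """Multi-kingdom co-occurrence network on matched samples.

    Samples are matched across kingdoms via (animal_id, age_group);
    relative abundances are computed within each kingdom before taxa are
    pooled.  Node attributes carry the kingdom and mean relative abundance.
    """
    if len(tables) < 2:
        raise ValueError("meta network needs at least two kingdoms")
    keys_per_kingdom = {}
    for kd, tab in tables.items():
        meta = metadata.frame.loc[tab.sample_ids]
        keys_per_kingdom[kd] = dict(
            zip(zip(meta["animal_id"], meta["age_group"]), tab.sample_ids)
        )
    shared = set.intersection(*(set(m) for m in keys_per_kingdom.values()))
    if not shared:
        raise ValueError("no samples matched across kingdoms")
    shared = sorted(shared)
    blocks, node_attrs = [], {}
    for kd, tab in tables.items():
        ids = [keys_per_kingdom[kd][key] for key in shared]
        rel = relative_abundance(tab).loc[ids]
        if taxa_per_kingdom is not None:
            keep = [t for t in rel.columns if t in taxa_per_kingdom.get(kd, set())]
            rel = rel[keep]
        rel = rel.rename(columns={c: f"{kd}:{c}" for c in rel.columns})
        rel.index = pd.RangeIndex(len(shared))
        blocks.append(rel)
        for col in rel.columns:
            node_attrs[col] = {"kingdom": kd, "mean_relabund": float(rel[col].mean())}
    pooled = pd.concat(blocks, axis=1)
    corr = spearman_matrix(pooled)
    if regime == "core":
        return build_core_network(corr, rho_min if rho_min is not None else 0.3,
                                  q_max, node_attrs)
    if regime == "age_specific":
        return build_age_specific_network(
            corr, rho_min if rho_min is not None else 0.5, node_attrs)
    raise ValueError(f"unknown regime {regime!r}")


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"taxon_a": a, "taxon_b": b, "rho": d.get("rho"), "sign": d.get("sign")}
        for a, b, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "sign"]).to_csv(
        path, sep="\t", index=False
    )
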