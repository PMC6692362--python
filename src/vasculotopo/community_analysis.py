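"""Louvain community structure and meta-network connectivity.

The vascular graph is partitioned by greedy modularity maximisation (Louvain
unfolding), retaining every intermediate level; the final level is the
partition at maximum modularity

    Q = (1/2m) sum_ij [A_ij - k_i k_j / (2m)] delta(c_i, c_j),

with the weighted adjacency convention that a self-loop of weight w
contributes A_ii = 2w to both the degree k_i and the internal sum.

Each community j is characterised by its node count n_j, internal edge count
e_j, perimeter P_j (edges to other communities), node centroid r_j, spatial
extent R_j (mean node distance from the centroid), and community degree
k_c = 2 e_j + P_j. Communities become weighted meta-nodes; meta-edge weights
count the vessel segments crossing between two communities. Meta-network
topology (C_c, L_c, D_c, degree histograms, assortativity) is computed on
the simple unweighted meta-graph.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._robust import FitResult, robust_loglog_fit
from .skeleton_graph import VascularGraph
from .topology_metrics import clustering_coefficients, shortest_path_stats


def _as_nx(graph):
    return graph.graph if isinstance(graph, VascularGraph) else graph


def modularity(graph, assignment: dict, weight: str | None = None) -> float:
    """Exact evaluation of the modularity Q of a node->community assignment.

    ``weight`` names an edge attribute (None = unweighted). Every node must
    be assigned; raises on an empty edge set (m = 0 leaves Q undefined).
    """
    g = _as_nx(graph)
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValueError(f"{len(missing)} node(s) without community assignment")
    m = g.size(weight=weight)
    if m == 0:
        raise ValueError("modularity undefined on an empty edge set")
    internal = {}  # community -> internal edge weight (self-loops once)
    degree = {}  # community -> total degree (self-loops twice)
    for u, v, d in g.edges(data=True):
        w = 1.0 if weight is None else float(d.get(weight, 1.0))
        cu, cv = assignment[u], assignment[v]
        degree[cu] = degree.get(cu, 0.0) + w
        degree[cv] = degree.get(cv, 0.0) + w
        if cu == cv:
            internal[cu] = internal.get(cu, 0.0) + w
    q = 0.0
    for c, dtot in degree.items():
        q += internal.get(c, 0.0) / m - (dtot / (2.0 * m)) ** 2
    return q


@dataclass
class CommunityPartition:
    """Louvain unfolding result: every level's assignment with its Q."""

    levels: list  # [(assignment dict, Q), ...] coarsening left to right
    seed: int

    @property
    def final(self) -> dict:
        return self.levels[-1][0]

    @property
    def q_final(self) -> float:
        return self.levels[-1][1]

    @property
    def n_communities(self) -> int:
        return len(set(self.final.values()))

    def communities(self) -> dict:
        out = {}
        for node, c in self.final.items():
            out.setdefault(c, set()).add(node)
        return out


def louvain_unfold(
    graph, seed: int = 0, weight: str | None = None, restarts: int = 5
) -> CommunityPartition:
    """Louvain community unfolding with all intermediate levels retained.

    Starts from singleton communities, greedily moves nodes between
    neighbouring communities while Q increases, then recurses on the induced
    meta-network; Q is non-decreasing over levels. The node sweep order is
    randomised: ``restarts`` independent runs (seeds derived from ``seed``)
    are performed and the run with the best final Q is returned, making the
    result a pure function of (graph, seed, restarts).
    """
    g = _as_nx(graph)
    if g.number_of_edges() == 0:
        raise ValueError("Louvain needs at least one edge")
    best = None
    for r in range(restarts):
        run_seed = seed + r
        levels = []
        for partition in nx.community.louvain_partitions(g, weight=weight, seed=run_seed):
            assignment = {}
            for cid, nodes in enumerate(partition):
                for n in nodes:
                    assignment[n] = cid
            levels.append((assignment, modularity(g, assignment, weight=weight)))
        if not levels:
            # single-level degenerate graphs: fall back to louvain_communities
            comms = nx.community.louvain_communities(g, weight=weight, seed=run_seed)
            assignment = {n: i for i, c in enumerate(comms) for n in c}
            levels = [(assignment, modularity(g, assignment, weight=weight))]
        if best is None or levels[-1][1] > best.q_final:
            best = CommunityPartition(levels, seed=run_seed)
    return best


def community_structure(graph, assignment: dict) -> pd.DataFrame:
    """Per-community records: n, e, P, centroid, extent R, k_c = 2e + P.

    Node positions are read from the ``pos_um`` node attribute; centroid and
    extent are NaN when positions are absent.
    """
    g = _as_nx(graph)
    comms = {}
    for n in g.nodes:
        if n in assignment:  # nodes of filtered-out communities are skipped
            comms.setdefault(assignment[n], []).append(n)
    e = {c: 0 for c in comms}
    p = {c: 0 for c in comms}
    for u, v in g.edges():
        if u not in assignment or v not in assignment:
            continue
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            e[cu] += 1
        else:
            p[cu] += 1
            p[cv] += 1
    rows = []
    for c, members in sorted(comms.items()):
        pos = [g.nodes[n].get("pos_um") for n in members]
        if all(x is not None for x in pos):
            pos = np.asarray(pos, float)
            centroid = pos.mean(axis=0)
            extent = float(np.linalg.norm(pos - centroid, axis=1).mean())
        else:
            centroid = np.full(3, np.nan)
            extent = np.nan
        rows.append(
            {
                "community": c,
                "n": len(members),
                "e": e[c],
                "P": p[c],
                "k_c": 2 * e[c] + p[c],
                "e_over_P": e[c] / p[c] if p[c] > 0 else np.nan,
                "centroid_z": centroid[0],
                "centroid_y": centroid[1],
                "centroid_x": centroid[2],
                "R_um": extent,
            }
        )
    return pd.DataFrame(rows)


def filter_isolated_communities(
    graph, assignment: dict, min_edges: int = 20
) -> tuple[dict, dict]:
    """Drop isolated communities (perimeter P = 0) with fewer than
    ``min_edges`` internal edges — disconnected boundary clippings.

    Returns (filtered assignment, log dict with removal counts).
    """
    records = community_structure(graph, assignment)
    drop = set(records.loc[(records["P"] == 0) & (records["e"] < min_edges), "community"])
    kept = {n: c for n, c in assignment.items() if c not in drop}
    log = {
        "n_communities_before": len(records),
        "n_removed": len(drop),
        "n_nodes_removed": sum(1 for c in assignment.values() if c in drop),
    }
    return kept, log


@dataclass
class MetaNetwork:
    """Communities as weighted meta-nodes.

    ``graph`` is a simple nx.Graph whose nodes are community ids carrying the
    structure record (n, e, P, k_c, centroid, R) and whose edge weights count
    intercommunity vessel segments.
    """

    graph: nx.Graph
    records: pd.DataFrame
    n_intercommunity_edges: int
    tissue_volume_mm3: float | None = None

    @property
    def n_communities(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def rho_c(self) -> float | None:
        if not self.tissue_volume_mm3:
            return None
        return self.n_communities / self.tissue_volume_mm3

    @property
    def rho_ice(self) -> float | None:
        if not self.tissue_volume_mm3:
            return None
        return self.n_intercommunity_edges / self.tissue_volume_mm3

    def community_degrees(self) -> np.ndarray:
        return np.array([self.graph.nodes[c]["k_c"] for c in self.graph.nodes], float)

    def unique_neighbor_counts(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()], float)

    def centroids(self) -> dict:
        return {
            c: np.array(
                [self.graph.nodes[c][k] for k in ("centroid_z", "centroid_y", "centroid_x")]
            )
            for c in self.graph.nodes
        }


def build_meta_network(
    graph, assignment: dict, tissue_volume_mm3: float | None = None
) -> MetaNetwork:
    """Collapse communities into a weighted meta-network.

    One meta-edge per community pair with at least one crossing vessel
    segment; its weight is the crossing-segment count, so the weight sum
    equals the number of intercommunity edges N_ice = sum_j P_j / 2.
    """
    g = _as_nx(graph)
    records = community_structure(g, assignment)
    meta = nx.Graph()
    for _, row in records.iterrows():
        meta.add_node(int(row["community"]), **{k: row[k] for k in records.columns if k != "community"})
    n_ice = 0
    for u, v in g.edges():
        if u not in assignment or v not in assignment:
            continue
        cu, cv = assignment[u], assignment[v]
        if cu != cv:
            n_ice += 1
            if meta.has_edge(cu, cv):
                meta[cu][cv]["weight"] += 1
            else:
                meta.add_edge(cu, cv, weight=1)
    return MetaNetwork(meta, records, n_ice, tissue_volume_mm3)


def meta_topology(meta: MetaNetwork, seed: int = 0) -> dict:
    """Topology of the simple unweighted meta-graph: C_c, L_c, D_c, the
    log-binned community-degree histogram (10 bins per decade, geometric
    centers) and unique-neighbour statistics."""
    if meta.n_communities < 2:
        raise ValueError("need at least 2 communities")
    _, _, c_c = clustering_coefficients(meta.graph)
    L, D, exact = shortest_path_stats(meta.graph, exact_threshold=20000, seed=seed)
    kc = meta.community_degrees()
    kc = kc[kc > 0]
    if kc.size:
        lo = np.floor(np.log10(kc.min()) * 10) / 10
        hi = np.ceil(np.log10(kc.max()) * 10) / 10 + 1e-9
        edges = 10 ** np.arange(lo, hi + 0.1, 0.1)
        hist, edges = np.histogram(kc, bins=edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
    else:
        hist, centers = np.array([]), np.array([])
    kcu = meta.unique_neighbor_counts()
    return {
        "C_c": c_c,
        "L_c": L,
        "D_c": D,
        "exact_paths": exact,
        "k_c_hist": hist,
        "k_c_bin_centers": centers,
        "k_c_u_mean": float(kcu.mean()) if kcu.size else np.nan,
        "k_c_u": kcu,
    }


def fit_isolation_exponent(records: pd.DataFrame) -> FitResult:
    """Isolation scaling P(e) ~ e^xi over individual communities (robust
    fit); xi below ~2/3 indicates strongly isolated communities, values
    between 2/3 and 1 weak community structure."""
    sel = (records["e"] > 0) & (records["P"] > 0)
    return robust_loglog_fit(records.loc[sel, "e"], records.loc[sel, "P"], min_support=5)


def fit_assortativity(meta: MetaNetwork, weighted: bool = False) -> FitResult:
    """Assortativity exponent kappa from <k_c1>(k_c) ~ k_c^kappa.

    For each community, <k_c1> is the mean community degree over its unique
    meta-neighbours (unweighted by default; ``weighted`` weights neighbours
    by meta-edge multiplicity)."""
    g = meta.graph
    if g.number_of_nodes() < 5:
        return FitResult(np.nan, np.nan, np.nan, np.nan, g.number_of_nodes(), ok=False)
    kc, knn = [], []
    for c in g.nodes:
        nbrs = list(g.neighbors(c))
        if not nbrs:
            continue
        vals = np.array([g.nodes[b]["k_c"] for b in nbrs], float)
        if weighted:
            w = np.array([g[c][b]["weight"] for b in nbrs], float)
            knn.append(float((vals * w).sum() / w.sum()))
        else:
            knn.append(float(vals.mean()))
        kc.append(g.nodes[c]["k_c"])
    return robust_loglog_fit(kc, knn, min_support=5)


def path_length_vs_separation(meta: MetaNetwork, delta_um: float = 50.0) -> pd.DataFrame:
    """Geodesic hop count between connected community pairs, binned by the
    Euclidean centroid separation Delta with bin width ``delta_um``.

    Returns per-bin rows (bin_lo_um, bin_hi_um, mean_L_c, n_pairs); the pair
    counts sum to the number of connected community pairs.
    """
    g = meta.graph
    cents = meta.centroids()
    nodes = list(g.nodes)
    pairs = []
    for i, src in enumerate(nodes):
        dist = nx.single_source_shortest_path_length(g, src)
        for tgt in nodes[i + 1:]:
            if tgt in dist:
                sep = float(np.linalg.norm(cents[src] - cents[tgt]))
                pairs.append((sep, dist[tgt]))
    if not pairs:
        return pd.DataFrame(columns=["bin_lo_um", "bin_hi_um", "mean_L_c", "n_pairs"])
    seps = np.array([p[0] for p in pairs])
    hops = np.array([p[1] for p in pairs], float)
    idx = np.floor(seps / delta_um).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        rows.append(
            {
                "bin_lo_um": b * delta_um,
                "bin_hi_um": (b + 1) * delta_um,
                "mean_L_c": float(hops[sel].mean()),
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
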