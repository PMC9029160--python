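"""Node-level topology battery and targeted-removal disruptiveness.

For a node i with degree k_i the battery comprises the clustering
coefficient C_i, Burt's effective size S_i = k_i - 2t_i/k_i (unweighted
form, t_i = edges among neighbors), the local efficiency E_i (mean
inverse shortest-path length between i's neighbors inside the subgraph
G_i induced by the neighbors, i itself excluded), and the brokerage

    B_i = k_i - (k_i - 1) * E_i,

which ranges from 1 (fully redundant neighborhood, E_i = 1) to k_i
(neighbors pairwise unreachable without i, E_i = 0).  Excluding i from
G_i is what makes B_i detect brokers: neighbor-to-neighbor routes may
not pass through the node being scored.

Disruptiveness of a node ranking is measured by cumulative removal
against a degree-matched random-removal baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError


# ---------------------------------------------------------------------------
# per-node measures
# ---------------------------------------------------------------------------

def clustering_coefficient(graph: nx.Graph, node) -> float:
    """2 t_i / (k_i (k_i - 1)); zero for degree < 2."""
    neighbors = list(graph.neighbors(node))
    k = len(neighbors)
    if k < 2:
        return 0.0
    t = sum(
        1
        for a in range(k)
        for b in range(a + 1, k)
        if graph.has_edge(neighbors[a], neighbors[b])
    )
    return 2.0 * t / (k * (k - 1))


def effective_size(graph: nx.Graph, node) -> float:
    """Burt effective size, unweighted form S_i = k_i - 2 t_i / k_i."""
    neighbors = list(graph.neighbors(node))
    k = len(neighbors)
    if k == 0:
        return 0.0
    t = sum(
        1
        for a in range(k)
        for b in range(a + 1, k)
        if graph.has_edge(neighbors[a], neighbors[b])
    )
    return k - 2.0 * t / k


def local_efficiency(graph: nx.Graph, node, weight: str | None = None) -> float:
    """Mean inverse distance between i's neighbors within G_i (i excluded).

    Unreachable pairs contribute 0 (1/infinity); degree < 2 gives 0.
    ``weight`` switches to weighted shortest paths (e.g. the MI distance)
    for exploratory use; the default is the topological form.
    """
    neighbors = list(graph.neighbors(node))
    k = len(neighbors)
    if k < 2:
        return 0.0
    sub = graph.subgraph(neighbors)
    total = 0.0
    for a in range(k):
        if weight is None:
            dist = nx.single_source_shortest_path_length(sub, neighbors[a])
        else:
            dist = nx.single_source_dijkstra_path_length(
                sub, neighbors[a], weight=weight
            )
        for b in range(a + 1, k):
            d = dist.get(neighbors[b])
            if d:
                total += 1.0 / d
    return total / (k * (k - 1) / 2.0)


def brokerage(graph: nx.Graph, node, weight: str | None = None) -> float:
    """B_i = k_i - (k_i - 1) E_i; 0 for isolated nodes, 1 for pendants."""
    k = graph.degree(node)
    if k == 0:
        return 0.0
    return k - (k - 1) * local_efficiency(graph, node, weight=weight)


def normalized_brokerage(graph: nx.Graph, weight: str | None = None) -> dict:
    """Min-max normalization of B_i over non-isolated nodes.

    Isolated nodes map to 0; a degenerate range (all B_i equal) maps
    every non-isolated node to 1.
    """
    raw = {v: brokerage(graph, v, weight=weight) for v in graph.nodes}
    active = {v: b for v, b in raw.items() if graph.degree(v) >= 1}
    out = {v: 0.0 for v in graph.nodes}
    if not active:
        return out
    lo, hi = min(active.values()), max(active.values())
    for v, b in active.items():
        out[v] = 1.0 if hi == lo else (b - lo) / (hi - lo)
    return out


def articulation_and_bridges(graph: nx.Graph) -> tuple[set, set]:
    """Cut vertices and cut edges (edges as frozensets of endpoints)."""
    points = set(nx.articulation_points(graph))
    bridges = {frozenset(e) for e in nx.bridges(graph)}
    return points, bridges


@dataclass
class NodeTopology:
    node_id: str
    degree: int
    clustering: float
    effective_size: float
    local_efficiency: float
    brokerage: float
    normalized_brokerage: float
    is_articulation: bool


def node_topology_table(graph: nx.Graph) -> pd.DataFrame:
    """Full per-node battery as a DataFrame (betweenness for reference only)."""
    norm = normalized_brokerage(graph)
    points, _ = articulation_and_bridges(graph)
    betweenness = nx.betweenness_centrality(graph)
    rows = []
    for v in graph.nodes:
        rows.append(
            {
                "node_id": v,
                "biotype": graph.nodes[v].get("biotype", ""),
                "degree": graph.degree(v),
                "clustering": clustering_coefficient(graph, v),
                "effective_size": effective_size(graph, v),
                "local_efficiency": local_efficiency(graph, v),
                "brokerage": brokerage(graph, v),
                "normalized_brokerage": norm[v],
                "is_articulation": v in points,
                "betweenness": betweenness[v],
            }
        )
    return pd.DataFrame(rows).set_index("node_id")


# ---------------------------------------------------------------------------
# disruption
# ---------------------------------------------------------------------------

@dataclass
class DisruptionProfile:
    removed_ids: list
    n_components_after: list[int]
    giant_fraction_after: list[float]
    baseline_mean: list[float]
    baseline_p5: list[float]
    baseline_p95: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "removed_id": self.removed_ids,
                "n_components": self.n_components_after,
                "giant_fraction": self.giant_fraction_after,
                "baseline_mean": self.baseline_mean,
                "baseline_p5": self.baseline_p5,
                "baseline_p95": self.baseline_p95,
            },
            index=pd.RangeIndex(1, len(self.removed_ids) + 1, name="step"),
        )


def _giant_fraction(graph: nx.Graph, n_original: int) -> float:
    if graph.number_of_nodes() == 0:
        return 0.0
    return max(len(c) for c in nx.connected_components(graph)) / n_original


def disruption_profile(
    graph: nx.Graph,
    targets: list,
    n_random: int = 100,
    seed: int = 0,
    degree_window: int = 1,
    exclude_targets: bool = True,
) -> DisruptionProfile:
    """Cumulative targeted removal versus degree-matched random removal.

    After each removal step the component count and the giant-component
    fraction (relative to the original node count) are recorded.  The
    baseline repeats the removal with random nodes matched to each
    target's original degree within ±``degree_window`` (falling back to
    the nearest available degree), ``n_random`` times.  With
    ``exclude_targets`` (the default) the baseline draws from comparable
    *alternative* nodes: on small graphs a pool that contains the targets
    themselves would re-remove them in a non-negligible share of
    replicates and flatten the comparison.
    """
    targets = list(targets)
    if len(set(targets)) != len(targets):
        raise ConfigurationError("duplicate targets in removal list")
    missing = [t for t in targets if t not in graph]
    if missing:
        raise ConfigurationError(f"targets not in graph: {missing[:5]}")
    n0 = graph.number_of_nodes()
    degrees = dict(graph.degree())

    work = graph.copy()
    n_comp, giant = [], []
    for t in targets:
        work.remove_node(t)
        n_comp.append(nx.number_connected_components(work))
        giant.append(_giant_fraction(work, n0))

    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    target_set = set(targets)
    base = np.empty((n_random, len(targets)))
    for r in range(n_random):
        pool = set(nodes) - target_set if exclude_targets else set(nodes)
        if not pool:
            pool = set(nodes)
        work = graph.copy()
        for step, t in enumerate(targets):
            candidates = [
                v for v in pool if abs(degrees[v] - degrees[t]) <= degree_window
            ]
            if not candidates:
                nearest = min(abs(degrees[v] - degrees[t]) for v in pool)
                candidates = [
                    v for v in pool if abs(degrees[v] - degrees[t]) == nearest
                ]
            pick = candidates[rng.integers(len(candidates))]
            pool.discard(pick)
            work.remove_node(pick)
            base[r, step] = _giant_fraction(work, n0)

    return DisruptionProfile(
        removed_ids=targets,
        n_components_after=n_comp,
        giant_fraction_after=giant,
        baseline_mean=list(base.mean(axis=0)),
        baseline_p5=list(np.percentile(base, 5, axis=0)),
        baseline_p95=list(np.percentile(base, 95, axis=0)),
    )


# ---------------------------------------------------------------------------
# broker ranking
# ---------------------------------------------------------------------------

def rank_ncrna_brokers(graph: nx.Graph) -> list[tuple[str, float, list[str]]]:
    """ncRNA nodes by normalized brokerage (desc), ties by degree then id.

    Each entry carries the node's direct non-ncRNA interactors — the gene
    set that defines its functional context.  Isolated ncRNAs are not
    ranked.
    """
    norm = normalized_brokerage(graph)
    ncrnas = [v for v in graph.nodes if graph.nodes[v].get("is_ncrna")]
    ranked = sorted(
        (v for v in ncrnas if graph.degree(v) > 0),
        key=lambda v: (-norm[v], -graph.degree(v), str(v)),
    )
    return [
        (
            v,
            norm[v],
            sorted(
                u for u in graph.neighbors(v) if not graph.nodes[u].get("is_ncrna")
            ),
        )
        for v in ranked
    ]
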