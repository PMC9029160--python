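"""Overlapping module landscape from an influence-spreading function.

A damped random-walk influence matrix is accumulated as the geometric
series sum_t (alpha P)^t where P is the (weight-proportional)
row-stochastic transition matrix and alpha the per-step damping; each
row therefore sums to 1 / (1 - alpha).  Summing incoming influence
yields a community landscape over the nodes; its local maxima ("hills")
are the module cores, and every node receives an overlapping membership
strength in each module proportional to its influence on that module's
core.  This is deliberately a simplified member of the
influence-landscape family of overlapping community methods: a single
landscape level, with an optional meta-graph in place of a full module
hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import NumericalError


@dataclass
class ModuleLandscape:
    """Overlapping module structure of a graph."""

    membership: dict  # node -> {module_id -> strength in [0, 1]}
    landscape_height: dict  # node -> height
    module_cores: dict  # module_id -> core node (a local maximum)

    @property
    def n_modules(self) -> int:
        return len(self.module_cores)

    def membership_frame(self) -> pd.DataFrame:
        cols = sorted(self.module_cores)
        return pd.DataFrame(
            [[self.membership[n].get(m, 0.0) for m in cols] for n in self.membership],
            index=list(self.membership),
            columns=cols,
        )


def influence_matrix(
    graph: nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    weight: str | None = "weight",
) -> pd.DataFrame:
    """Damped-walk influence I = sum_t (alpha P)^t, iterated to L1 < tol.

    ``influence.loc[i, j]`` is the total flow j receives from a unit
    perturbation at i; rows sum to 1 / (1 - damping).  Edge weights (if
    the attribute is present) set the per-step flow proportions.
    """
    if not 0 < damping < 1:
        raise NumericalError("damping must be in (0, 1)")
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return pd.DataFrame()
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight=weight)
    row_sums = adj.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row_sums > 0, adj / np.where(row_sums == 0, 1, row_sums), 0.0)

    total = np.eye(n)
    term = np.eye(n)
    for _ in range(max_iter):
        term = damping * (term @ p)
        total += term
        residual = np.abs(term).sum()
        if residual < tol:
            return pd.DataFrame(total, index=nodes, columns=nodes)
    raise NumericalError(
        f"influence series did not converge (residual {residual:.3g})"
    )


def community_landscape(influence: pd.DataFrame) -> dict:
    """Landscape height of each node: total incoming influence."""
    return influence.sum(axis=0).to_dict()


def detect_hills(
    graph: nx.Graph, heights: dict, influence: pd.DataFrame
) -> ModuleLandscape:
    """Module cores = local maxima of the landscape; overlapping membership.

    A node is a core when its height is >= that of every neighbor, with
    exact ties broken toward the lexicographically smaller node id (so a
    flat plateau yields one core).  Membership of node n in the module
    cored at c is influence(n -> c) normalized across cores.
    """
    cores = []
    for v in graph.nodes:
        is_max = True
        for u in graph.neighbors(v):
            if heights[u] > heights[v] or (
                heights[u] == heights[v] and str(u) < str(v)
            ):
                is_max = False
                break
        if is_max:
            cores.append(v)
    cores.sort(key=str)
    module_cores = {f"M{i}": c for i, c in enumerate(cores)}

    membership: dict = {}
    for v in graph.nodes:
        strengths = {m: float(influence.loc[v, c]) for m, c in module_cores.items()}
        total = sum(strengths.values())
        if total > 0:
            strengths = {m: s / total for m, s in strengths.items()}
        membership[v] = strengths
    return ModuleLandscape(
        membership=membership,
        landscape_height={v: float(heights[v]) for v in graph.nodes},
        module_cores=module_cores,
    )


def module_landscape(
    graph: nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-8,
    weight: str | None = "weight",
) -> ModuleLandscape:
    """Convenience wrapper: influence -> landscape -> hills."""
    infl = influence_matrix(graph, damping=damping, tol=tol, weight=weight)
    heights = community_landscape(infl)
    return detect_hills(graph, heights, infl)


def membership_entropy(landscape: ModuleLandscape) -> dict:
    """Shannon entropy (bits) of each node's membership distribution.

    Nodes that straddle several modules — brokers — carry higher entropy
    than nodes buried inside a single module.
    """
    out = {}
    for v, strengths in landscape.membership.items():
        p = np.array([s for s in strengths.values() if s > 0])
        out[v] = float(-(p * np.log2(p)).sum()) if p.size else 0.0
    return out


def module_meta_graph(landscape: ModuleLandscape) -> nx.Graph:
    """One meta-level: modules as nodes, summed cross-membership as weight."""
    meta = nx.Graph()
    meta.add_nodes_from(landscape.module_cores)
    modules = list(landscape.module_cores)
    for a_i in range(len(modules)):
        for b_i in range(a_i + 1, len(modules)):
            a, b = modules[a_i], modules[b_i]
            w = sum(
                m.get(a, 0.0) * m.get(b, 0.0)
                for m in landscape.membership.values()
            )
            if w > 0:
                meta.add_edge(a, b, weight=w)
    return meta
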