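"""Template co-expression networks from mutual information.

Association between expression profiles is measured with a plug-in
mutual-information (MI) estimator on equal-frequency discretized values,
normalized to [0, 1] by the smaller marginal entropy so that the edge
distance d = 1 - MI is itself in [0, 1].  Edge significance comes from a
per-pair permutation null (sample order of one profile permuted), and
edge stability ("rewiring persistence") from subsampled rebuilds of the
edge set: the fraction of resamplings in which the edge's MI again
clears a size-matched null critical value.  An absolute-Spearman path
mirrors the MI path for metric-comparison reports, and a
degree-preserving edge-swap null is available for topology-level
comparisons.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .matrix import ExpressionMatrix

MIN_SAMPLES = 8


# ---------------------------------------------------------------------------
# discretization and MI
# ---------------------------------------------------------------------------

def default_bins(n_samples: int) -> int:
    """Bin count for the joint histogram: ceil(sqrt(n / 5)), at least 3.

    Chosen so the b x b joint table keeps >= ~5 expected counts per cell;
    finer grids (e.g. sqrt(n)) leave the plug-in estimate dominated by
    sparsity noise at cohort sizes of 100-250 samples.
    """
    return max(3, int(np.ceil(np.sqrt(n_samples / 5.0))))


def discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning via the (stable) rank order.

    Ties are split deterministically by original position, so identical
    vectors receive identical labels.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    labels[order] = (np.arange(n) * n_bins) // n
    return labels


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mi_from_labels(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Normalized plug-in MI of two label vectors: MI / min(H(X), H(Y))."""
    joint = np.bincount(x * n_bins + y, minlength=n_bins * n_bins)
    hx = _entropy_from_counts(np.bincount(x, minlength=n_bins))
    hy = _entropy_from_counts(np.bincount(y, minlength=n_bins))
    if hx == 0.0 or hy == 0.0:
        return 0.0
    hxy = _entropy_from_counts(joint)
    mi = hx + hy - hxy
    return float(np.clip(mi / min(hx, hy), 0.0, 1.0))


def pairwise_mi(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Symmetric normalized-MI matrix over the requested genes.

    Constant genes have zero entropy; their normalized MI is defined as 0
    against any partner (including themselves).
    """
    genes = list(genes) if genes is not None else matrix.gene_ids
    values = matrix.values.loc[genes].to_numpy(dtype=float)
    n = values.shape[1]
    if n < MIN_SAMPLES:
        raise DataError(f"need >= {MIN_SAMPLES} samples for MI estimation")
    b = n_bins or default_bins(n)
    constant = values.std(axis=1) == 0
    labels = np.stack([discretize(row, b) for row in values])

    k = len(genes)
    out = np.zeros((k, k))
    for i in range(k):
        if constant[i]:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, k):
            if constant[j]:
                continue
            out[i, j] = out[j, i] = mi_from_labels(labels[i], labels[j], b)
    return pd.DataFrame(out, index=genes, columns=genes)


def pairwise_correlation(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric |Spearman rho| matrix (constant genes get 0)."""
    genes = list(genes) if genes is not None else matrix.gene_ids
    values = matrix.values.loc[genes].to_numpy(dtype=float)
    if values.shape[1] < MIN_SAMPLES:
        raise DataError(f"need >= {MIN_SAMPLES} samples")
    if len(genes) == 1:
        rho = np.array([[1.0]])
    elif len(genes) == 2:  # spearmanr returns a scalar for two variables
        with np.errstate(invalid="ignore"):
            r = stats.spearmanr(values[0], values[1]).statistic
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho, _ = stats.spearmanr(values, axis=1)
    rho = np.abs(np.nan_to_num(rho, nan=0.0))
    constant = values.std(axis=1) == 0
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, np.where(constant, 0.0, 1.0))
    return pd.DataFrame(rho, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class EdgeNull:
    """Permutation null of one edge's association score."""

    edge: tuple[str, str]
    observed: float
    null_samples: np.ndarray
    null_p: float

    def critical_value(self, alpha: float) -> float:
        """Null quantile the observed score must reach for p <= alpha."""
        return float(np.quantile(self.null_samples, 1.0 - alpha, method="higher"))


def permutation_null(
    matrix: ExpressionMatrix,
    pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    n_bins: int | None = None,
) -> EdgeNull:
    """MI permutation test for one gene pair.

    One profile's sample order is permuted independently per draw;
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 20:
        raise ConfigurationError("n_perm < 20 gives too coarse a p-value")
    x = matrix.values.loc[pair[0]].to_numpy(dtype=float)
    y = matrix.values.loc[pair[1]].to_numpy(dtype=float)
    b = n_bins or default_bins(len(x))
    rng = np.random.default_rng(seed)
    lx, ly = discretize(x, b), discretize(y, b)
    if x.std() == 0 or y.std() == 0:
        null = np.zeros(n_perm)
        return EdgeNull(pair, 0.0, null, 1.0)
    observed = mi_from_labels(lx, ly, b)
    null = _mi_null_samples(lx, ly, b, n_perm, rng)
    p = (1 + int((null >= observed - 1e-15).sum())) / (1 + n_perm)
    return EdgeNull(pair, observed, null, p)


def _mi_null_samples(
    lx: np.ndarray, ly: np.ndarray, b: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized normalized-MI null: marginals are permutation-invariant."""
    n = len(lx)
    hx = _entropy_from_counts(np.bincount(lx, minlength=b))
    hy = _entropy_from_counts(np.bincount(ly, minlength=b))
    perms = rng.permuted(np.tile(ly, (n_perm, 1)), axis=1)
    flat = (np.arange(n_perm)[:, None] * b * b + lx[None, :] * b + perms).ravel()
    counts = np.bincount(flat, minlength=n_perm * b * b).reshape(n_perm, b * b)
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    hxy = -plogp.sum(axis=1)
    mi = hx + hy - hxy
    return np.clip(mi / min(hx, hy), 0.0, 1.0)


# ---------------------------------------------------------------------------
# bootstrap persistence
# ---------------------------------------------------------------------------

def rewiring_persistence(
    matrix: ExpressionMatrix,
    edges: list[tuple[str, str]],
    thresholds: dict[tuple[str, str], float] | float | None = None,
    n_randomizations: int = 100,
    seed: int = 0,
    n_bins: int | None = None,
    subsample: float = 0.8,
    alpha: float = 0.05,
    null_draws: int = 1000,
) -> dict[tuple[str, str], float]:
    """Fraction of sample-resampled rebuilds in which each edge reappears.

    Each rebuild draws ``subsample`` of the samples *without* replacement
    (with-replacement bootstrap is avoided because duplicated samples
    sharpen the joint histogram and bias plug-in MI upward for every
    pair).  An edge reappears when its recomputed normalized MI reaches
    the rebuild threshold: by default the (1 - alpha) quantile of the
    independence null at the subsample size, shared across edges since
    equal-frequency marginals make the null universal.  Explicit
    ``thresholds`` (scalar or per-edge) override the simulated null.
    """
    n = matrix.n_samples
    if n < MIN_SAMPLES:
        raise DataError(f"need >= {MIN_SAMPLES} samples")
    if n_randomizations < 1:
        raise ConfigurationError("n_randomizations must be >= 1")
    if not 0 < subsample <= 1:
        raise ConfigurationError("subsample must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n2 = max(MIN_SAMPLES, int(round(subsample * n)))
    n2 = min(n2, n)
    b = n_bins or default_bins(n)
    if thresholds is None:
        # independence null at the rebuild size, uniform marginals
        base = (np.arange(n2) * b) // n2
        null = _mi_null_samples(base, base, b, null_draws, rng)
        thresholds = float(np.quantile(null, 1.0 - alpha, method="higher"))
    nodes = sorted({u for e in edges for u in e})
    values = {g: matrix.values.loc[g].to_numpy(dtype=float) for g in nodes}

    hits = {e: 0 for e in edges}
    for _ in range(n_randomizations):
        idx = rng.choice(n, size=n2, replace=False)
        labels = {g: discretize(v[idx], b) for g, v in values.items()}
        for e in edges:
            mi = mi_from_labels(labels[e[0]], labels[e[1]], b)
            cut = thresholds[e] if isinstance(thresholds, dict) else thresholds
            if mi >= cut:
                hits[e] += 1
    return {e: h / n_randomizations for e, h in hits.items()}


# ---------------------------------------------------------------------------
# template network assembly
# ---------------------------------------------------------------------------

def build_template_network(
    matrix: ExpressionMatrix,
    genes: list[str],
    ncrnas: list[str],
    alpha: float = 0.05,
    min_persistence: float = 0.8,
    n_perm: int = 1000,
    n_boot: int = 100,
    seed: int = 0,
    n_bins: int | None = None,
    metric: str = "mi",
    log2_fc: dict[str, float] | None = None,
    signed: bool = False,
) -> nx.Graph:
    """Assemble the template network over signature genes plus ncRNAs.

    Edges are kept iff their permutation p-value is <= ``alpha`` and
    their resampling persistence is >= ``min_persistence``.  Isolated
    nodes stay in the graph flagged ``isolated=True``; every edge stores
    mi, distance = 1 - mi, null_p and persistence.

    With ``signed=True`` only positively associated pairs (Spearman
    rho > 0) become edges — the signed-co-expression convention.  MI is
    sign-blind, and quantile normalization induces weak systematic
    anti-correlation between unrelated strongly-shifted genes
    (compositional displacement on the shared quantile scale), which an
    unsigned network would admit as spurious bridges.
    """
    if not genes:
        raise DataError("empty gene list: no signature biclusters selected?")
    if metric not in ("mi", "cor"):
        raise ConfigurationError(f"unknown metric: {metric!r}")
    node_ids = list(dict.fromkeys(list(genes) + list(ncrnas)))
    ncrna_set = set(ncrnas)
    values = matrix.values.loc[node_ids].to_numpy(dtype=float)
    n = values.shape[1]
    if n < MIN_SAMPLES:
        raise DataError(f"need >= {MIN_SAMPLES} samples")
    b = n_bins or default_bins(n)
    rng = np.random.default_rng(seed)

    graph = nx.Graph(metric=metric.upper(), alpha=alpha, min_persistence=min_persistence)
    for g in node_ids:
        graph.add_node(
            g,
            biotype=matrix.biotype.get(g, "unannotated"),
            is_ncrna=g in ncrna_set,
            log2_fc=float((log2_fc or {}).get(g, 0.0)),
        )

    if alpha <= 0:  # the +1-corrected p can never be <= 0
        for g in node_ids:
            graph.nodes[g]["isolated"] = True
        return graph

    labels = np.stack([discretize(row, b) for row in values])
    constant = values.std(axis=1) == 0

    candidates: list[tuple[str, str]] = []
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    k = len(node_ids)
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                continue
            # per-pair seed and canonical orientation from the unordered
            # pair identity, so the edge set does not depend on gene
            # input order
            lo, hi = sorted((i, j), key=lambda t: node_ids[t])
            tag = f"{node_ids[lo]}|{node_ids[hi]}"
            pair_rng = np.random.default_rng(
                (seed + zlib.crc32(tag.encode())) % (2**31)
            )
            if metric == "mi":
                obs = mi_from_labels(labels[lo], labels[hi], b)
                null = _mi_null_samples(
                    labels[lo], labels[hi], b, n_perm, pair_rng
                )
            else:
                obs = _abs_spearman(values[lo], values[hi])
                null = _cor_null_samples(values[lo], values[hi], n_perm, pair_rng)
            p = (1 + int((null >= obs - 1e-15).sum())) / (1 + n_perm)
            if p <= alpha:
                if signed:
                    rho = stats.spearmanr(values[lo], values[hi]).statistic
                    if not rho > 0:
                        continue
                e = (node_ids[i], node_ids[j])
                candidates.append(e)
                scores[e] = (obs, p)

    if candidates and min_persistence > 0:
        if metric == "mi":
            persistence = rewiring_persistence(
                matrix,
                candidates,
                n_randomizations=n_boot,
                seed=int(rng.integers(2**31)),
                n_bins=b,
                alpha=alpha,
            )
        else:
            persistence = _cor_persistence(
                matrix, candidates, n_boot, int(rng.integers(2**31)), alpha
            )
    else:
        persistence = {e: 1.0 for e in candidates}

    for e in candidates:
        if persistence[e] >= min_persistence:
            obs, p = scores[e]
            graph.add_edge(
                e[0],
                e[1],
                mi=obs,
                distance=1.0 - obs,
                null_p=p,
                persistence=persistence[e],
            )
    for g in node_ids:
        graph.nodes[g]["isolated"] = graph.degree(g) == 0
    return graph


def _cor_persistence(
    matrix: ExpressionMatrix,
    edges: list[tuple[str, str]],
    n_randomizations: int,
    seed: int,
    alpha: float,
    subsample: float = 0.8,
    null_draws: int = 1000,
) -> dict[tuple[str, str], float]:
    """|Spearman| analogue of :func:`rewiring_persistence`."""
    n = matrix.n_samples
    n2 = max(MIN_SAMPLES, min(n, int(round(subsample * n))))
    rng = np.random.default_rng(seed)
    base = np.arange(n2, dtype=float)
    null = _cor_null_samples(base, base, null_draws, rng)
    crit = float(np.quantile(null, 1.0 - alpha, method="higher"))
    nodes = sorted({u for e in edges for u in e})
    values = {g: matrix.values.loc[g].to_numpy(dtype=float) for g in nodes}
    hits = {e: 0 for e in edges}
    for _ in range(n_randomizations):
        idx = rng.choice(n, size=n2, replace=False)
        for e in edges:
            if _abs_spearman(values[e[0]][idx], values[e[1]][idx]) >= crit:
                hits[e] += 1
    return {e: h / n_randomizations for e, h in hits.items()}


def _abs_spearman(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return float(abs(np.nan_to_num(rho, nan=0.0)))


def _cor_null_samples(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rx_c = rx - rx.mean()
    p_c = perms - perms.mean(axis=1, keepdims=True)
    num = p_c @ rx_c
    den = np.linalg.norm(rx_c) * np.linalg.norm(p_c, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return np.abs(rho)


def degree_swap_null(
    graph: nx.Graph, n_swaps: int | None = None, seed: int = 0
) -> nx.Graph:
    """Degree-preserving rewired copy of a network (edge-swap null).

    Complements the data-driven persistence filter with a topology-level
    null: node degrees are preserved exactly while all higher-order
    structure (clustering, modules, bridges) is randomized.  Edge
    attributes are not carried over.
    """
    null = nx.Graph()
    null.add_nodes_from(graph.nodes(data=True))
    null.add_edges_from(graph.edges())
    if null.number_of_edges() < 2:
        return null
    n_swaps = n_swaps if n_swaps is not None else 10 * null.number_of_edges()
    nx.double_edge_swap(
        null, nswap=n_swaps, max_tries=100 * n_swaps,
        seed=np.random.default_rng(seed),
    )
    return null
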