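"""Iterative Signature Algorithm (ISA) biclustering with robustness
scoring, size/robustness filters and subtype-dominance selection.

ISA alternates two thresholded scoring steps until a self-consistent
bicluster B = (I, J) emerges: samples are scored by the current gene set
on the row-standardized matrix, genes are scored by the kept samples on
the column-standardized matrix, and only entries whose |z| exceeds the
respective threshold (with a coherent sign) are kept.  Fixed points are
deduplicated by gene-set Jaccard similarity.

Robustness compares the fixed-point score against the best score ISA can
reach on a row-and-column shuffled copy of the matrix; both the raw
score and the ratio to the shuffled maximum are reported, and the filter
accepts either metric by name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .matrix import ExpressionMatrix


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Bicluster:
    """A converged gene-set x sample-set pair with its z-score weights."""

    genes: list[str]
    samples: list[str]
    gene_scores: dict[str, float]
    sample_scores: dict[str, float]
    score: float
    thresholds: tuple[float, float]  # (gene, sample)
    robustness: float | None = None  # raw fixed-point score scale
    robustness_ratio: float | None = None

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def sample_set(self) -> frozenset[str]:
        return frozenset(self.samples)


@dataclass
class BiclusterSet:
    biclusters: list[Bicluster]
    gene_thresholds: list[float]
    sample_thresholds: list[float]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, i: int) -> Bicluster:
        return self.biclusters[i]


@dataclass
class RobustnessResult:
    raw: float
    ratio: float
    shuffled_max: float


# ---------------------------------------------------------------------------
# standardization and the ISA step
# ---------------------------------------------------------------------------

class StandardizedMatrix:
    """Row- and column-standardized copies of an expression matrix.

    ``row_std`` (genes z-scored across samples) scores samples;
    ``col_std`` (samples z-scored across genes) scores genes.
    Constant rows/columns standardize to zero rather than NaN.
    """

    def __init__(self, matrix: ExpressionMatrix):
        values = matrix.array()
        self.gene_ids = list(matrix.gene_ids)
        self.sample_ids = list(matrix.sample_ids)
        self.row_std = _safe_zscore(values, axis=1)
        self.col_std = _safe_zscore(values, axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.row_std.shape


def _safe_zscore(a: np.ndarray, axis: int) -> np.ndarray:
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mean) / sd


def _threshold_dominant(z: np.ndarray, threshold: float) -> tuple[np.ndarray, int]:
    """Indices with |z| above threshold restricted to the dominant sign."""
    above = np.abs(z) > threshold
    if not above.any():
        return np.empty(0, dtype=int), 1
    sign = 1 if z[above].sum() >= 0 else -1
    keep = above & (np.sign(z) == sign)
    return np.nonzero(keep)[0], sign


def isa_step(
    std: StandardizedMatrix,
    gene_idx: np.ndarray,
    gene_threshold: float,
    sample_threshold: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One full ISA refinement from a gene membership set.

    Returns ``(new_gene_idx, gene_z, sample_idx, sample_z)``; empty index
    arrays signal a dead seed.  A bicluster is a fixed point of this map,
    which is a pure function of the gene set — re-applying it to a
    converged bicluster must leave membership unchanged.
    """
    empty = np.empty(0, dtype=int)
    if len(gene_idx) == 0:
        return empty, np.empty(0), empty, np.empty(0)
    # score samples by the gene signature
    s_raw = std.row_std[gene_idx].mean(axis=0)
    s_z = (s_raw - s_raw.mean()) / (s_raw.std() or 1.0)
    sample_idx, s_sign = _threshold_dominant(s_z, sample_threshold)
    if len(sample_idx) == 0:
        return empty, np.empty(0), empty, np.empty(0)
    # score genes by the kept samples, weighted by their (positive) z
    weights = s_sign * s_z[sample_idx]
    g_raw = std.col_std[:, sample_idx] @ weights / weights.sum()
    g_z = (g_raw - g_raw.mean()) / (g_raw.std() or 1.0)
    new_gene_idx, _ = _threshold_dominant(g_z, gene_threshold)
    return new_gene_idx, g_z, sample_idx, s_z


# ---------------------------------------------------------------------------
# the main run
# ---------------------------------------------------------------------------

def isa_run(
    matrix: ExpressionMatrix,
    gene_thresholds: list[float] | None = None,
    sample_thresholds: list[float] | None = None,
    n_seeds: int = 100,
    seed: int = 0,
    max_iter: int = 100,
    seed_sparsity: float = 0.02,
    dedup_jaccard: float = 0.9,
) -> BiclusterSet:
    """Run ISA from random sparse gene seeds over a threshold grid.

    Fixed points reached from any (seed, threshold pair) combination are
    pooled and deduplicated at gene-set Jaccard > ``dedup_jaccard``
    (ties resolved toward the higher-scoring bicluster).  Deterministic
    given ``seed``.
    """
    if gene_thresholds is None:
        gene_thresholds = [1.5, 2.0, 2.5, 3.0]
    if sample_thresholds is None:
        sample_thresholds = [1.0, 1.5, 2.0]
    std = StandardizedMatrix(matrix)
    n_genes = std.shape[0]
    if n_genes == 0:
        return BiclusterSet([], gene_thresholds, sample_thresholds, seed)

    rng = np.random.default_rng(seed)
    k = max(3, int(round(seed_sparsity * n_genes)))
    seed_sets = [
        rng.choice(n_genes, size=min(k, n_genes), replace=False)
        for _ in range(n_seeds)
    ]

    found: list[Bicluster] = []
    for tg in gene_thresholds:
        for ts in sample_thresholds:
            for s0 in seed_sets:
                bc = _converge(std, s0, tg, ts, max_iter)
                if bc is not None:
                    found.append(bc)
    deduped = deduplicate(found, dedup_jaccard)
    return BiclusterSet(deduped, gene_thresholds, sample_thresholds, seed)


def _converge(
    std: StandardizedMatrix,
    gene_idx: np.ndarray,
    tg: float,
    ts: float,
    max_iter: int,
) -> Bicluster | None:
    prev: frozenset[int] | None = None
    prev_gz: np.ndarray | None = None
    corr_hits = 0
    for _ in range(max_iter):
        new_idx, g_z, s_idx, s_z = isa_step(std, gene_idx, tg, ts)
        if len(new_idx) == 0 or len(s_idx) == 0:
            return None
        current = frozenset(new_idx.tolist())
        if prev_gz is not None and g_z.std() > 0 and prev_gz.std() > 0:
            corr = float(np.corrcoef(g_z, prev_gz)[0, 1])
            corr_hits = corr_hits + 1 if corr > 0.99 else 0
        converged = current == prev or corr_hits >= 2
        prev, prev_gz, gene_idx = current, g_z, new_idx
        if converged:
            # one more step to make membership exactly self-consistent
            final_idx, g_z, s_idx, s_z = isa_step(std, new_idx, tg, ts)
            if len(final_idx) == 0 or frozenset(final_idx.tolist()) != current:
                continue
            return _package(std, final_idx, g_z, s_idx, s_z, tg, ts)
    return None


def _package(std, gene_idx, g_z, sample_idx, s_z, tg, ts) -> Bicluster:
    genes = [std.gene_ids[i] for i in gene_idx]
    samples = [std.sample_ids[j] for j in sample_idx]
    # bilinear fixed-point score u'Ev with unit-norm score weights: the
    # coherence the bicluster extracts from the row-standardized matrix
    # (a leading-singular-value analogue restricted to the fixed point).
    # Unlike a plain size product it does not reward large noise modules.
    u = g_z[gene_idx] / (np.linalg.norm(g_z[gene_idx]) or 1.0)
    v = s_z[sample_idx] / (np.linalg.norm(s_z[sample_idx]) or 1.0)
    sub = std.row_std[np.ix_(gene_idx, sample_idx)]
    score = float(abs(u @ sub @ v))
    return Bicluster(
        genes=genes,
        samples=samples,
        gene_scores={g: float(g_z[i]) for g, i in zip(genes, gene_idx)},
        sample_scores={s: float(s_z[j]) for s, j in zip(samples, sample_idx)},
        score=score,
        thresholds=(tg, ts),
    )


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    if not a and not b:
        return 1.0
    return len(set(a) & set(b)) / len(set(a) | set(b))


def deduplicate(biclusters: list[Bicluster], cut: float = 0.9) -> list[Bicluster]:
    """Greedy dedup by gene-set Jaccard, keeping the higher-scoring one.

    Candidates are sorted by (score desc, gene tuple) first, so the result
    does not depend on the enumeration order of seeds.
    """
    ordered = sorted(
        biclusters, key=lambda b: (-b.score, tuple(sorted(b.genes)))
    )
    kept: list[Bicluster] = []
    for cand in ordered:
        if all(jaccard(cand.gene_set, k.gene_set) <= cut for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def isa_robustness(
    bicluster: Bicluster,
    matrix: ExpressionMatrix,
    n_shuffles: int = 5,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 100,
) -> RobustnessResult:
    """Score stability against row-and-column shuffled data.

    The bicluster's raw fixed-point score is compared with the maximum
    score ISA attains (same thresholds, random restarts) on shuffled
    copies of the matrix in which every row and then every column is
    independently permuted.  Updates the bicluster in place and returns
    both the raw score and the ratio to the shuffled maximum.
    """
    if n_shuffles <= 0:
        raise ConfigurationError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    tg, ts = bicluster.thresholds
    values = matrix.array()
    n_genes, _ = values.shape
    k = max(3, len(bicluster.genes))

    best_null = 0.0
    for _ in range(n_shuffles):
        shuffled = values.copy()
        for i in range(shuffled.shape[0]):
            rng.shuffle(shuffled[i])
        for j in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, j])
        frame = pd.DataFrame(
            shuffled, index=matrix.values.index, columns=matrix.values.columns
        )
        std = StandardizedMatrix(matrix.with_values(frame))
        own = np.array(
            [std.gene_ids.index(g) for g in bicluster.genes if g in std.gene_ids]
        )
        if len(own):  # re-run from the bicluster's own seed genes
            bc = _converge(std, own, tg, ts, max_iter)
            if bc is not None:
                best_null = max(best_null, bc.score)
        for _ in range(n_restarts):
            s0 = rng.choice(n_genes, size=min(k, n_genes), replace=False)
            bc = _converge(std, s0, tg, ts, max_iter)
            if bc is not None:
                best_null = max(best_null, bc.score)
    # a noise floor: one-gene, one-sample signature at the thresholds
    floor = max(best_null, tg * ts, 1e-12)
    result = RobustnessResult(
        raw=bicluster.score, ratio=bicluster.score / floor, shuffled_max=best_null
    )
    bicluster.robustness = result.raw
    bicluster.robustness_ratio = result.ratio
    return result


def filter_biclusters(
    bset: BiclusterSet,
    min_genes: int = 10,
    min_samples: int = 7,
    min_robustness: float = 0.0,
    metric: str = "ratio",
) -> BiclusterSet:
    """Apply the size and robustness gates.

    ``metric`` selects which robustness scale the threshold refers to:
    ``"ratio"`` (to shuffled maximum) or ``"raw"`` (fixed-point score).
    """
    if metric not in ("ratio", "raw"):
        raise ConfigurationError(f"unknown robustness metric: {metric!r}")
    kept = []
    for bc in bset:
        if len(bc.genes) < min_genes or len(bc.samples) < min_samples:
            continue
        if min_robustness > 0:
            value = bc.robustness_ratio if metric == "ratio" else bc.robustness
            if value is None or value < min_robustness:
                continue
        kept.append(bc)
    return BiclusterSet(kept, bset.gene_thresholds, bset.sample_thresholds, bset.seed)


# ---------------------------------------------------------------------------
# subtype dominance
# ---------------------------------------------------------------------------

def subtype_fractions(
    bset: BiclusterSet | list[Bicluster],
    subtype: dict[str, str],
    group: dict[str, str] | None = None,
    by: str = "samples",
) -> pd.DataFrame:
    """Per-bicluster subtype composition.

    Returns a DataFrame indexed by bicluster number (1-based) with one
    column per subtype plus ``dominant_subtype`` / ``dominant_fraction``.
    Rows sum to 1 exactly.

    ``by="samples"`` (default) tabulates the member tumor samples'
    subtype labels (normal-group members excluded from the denominator);
    ``by="genes"`` tabulates member genes instead, for callers that
    carry a gene -> subtype association (e.g. signature-gene panels).
    """
    if by not in ("samples", "genes"):
        raise ConfigurationError(f"unknown composition mode: {by!r}")
    biclusters = list(bset)
    labels = sorted(set(subtype.values()))
    rows = []
    for idx, bc in enumerate(biclusters, start=1):
        if by == "genes":
            members = list(bc.genes)
        else:
            members = [
                s
                for s in bc.samples
                if group is None or group.get(s) == "tumor"
            ]
        unlabeled = [m for m in members if m not in subtype]
        if unlabeled:
            raise DataError(
                f"bicluster {idx}: {by[:-1]} {unlabeled[0]!r} has no subtype label"
            )
        if not members:
            raise DataError(f"bicluster {idx} has no labelled members")
        counts = pd.Series(0.0, index=labels)
        for s in members:
            counts[subtype[s]] += 1
        rows.append(counts / counts.sum())
    table = pd.DataFrame(rows, index=range(1, len(biclusters) + 1))
    table.index.name = "bicluster"
    return annotate_dominance(table)


def annotate_dominance(fractions: pd.DataFrame) -> pd.DataFrame:
    """Attach dominant_subtype / dominant_fraction columns to a fraction table."""
    frac = fractions.drop(
        columns=["dominant_subtype", "dominant_fraction"], errors="ignore"
    )
    table = frac.copy()
    table["dominant_subtype"] = frac.idxmax(axis=1)
    table["dominant_fraction"] = frac.max(axis=1)
    return table


def select_signature_biclusters(
    table: pd.DataFrame,
    mode: str = "strict",
    threshold: float = 0.5,
) -> list[tuple[int, str]]:
    """Pick the subtype-signature biclusters from a dominance table.

    ``strict`` keeps biclusters whose dominant subtype exceeds
    ``threshold`` (a prevalent-subtype majority rule); ``top_per_subtype``
    returns, for each subtype column, the bicluster maximizing that
    subtype's fraction.
    """
    if mode not in ("strict", "top_per_subtype"):
        raise ConfigurationError(f"unknown selection mode: {mode!r}")
    if table.empty:
        return []
    table = annotate_dominance(table)
    frac = table.drop(columns=["dominant_subtype", "dominant_fraction"])
    if mode == "strict":
        hits = table[table["dominant_fraction"] > threshold]
        return [
            (int(i), str(row["dominant_subtype"])) for i, row in hits.iterrows()
        ]
    return [(int(frac[col].idxmax()), str(col)) for col in frac.columns]
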