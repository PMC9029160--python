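"""Normalization and differential expression.

The preprocessing chain mirrors common microarray-style RNA-Seq practice
on FPKM-like values: quantile normalization across samples, log2
transform with a pseudocount, then a two-sample t-test of tumor versus
normal on the log2 scale with a raw p-value gate and a two-sided
fold-change gate.  The coefficient of variation (CV) is computed on the
linear scale across all samples and genes with CV = 0 (flat profiles)
never pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, StatisticalError
from .matrix import ExpressionMatrix

DE_COLUMNS = ["t_statistic", "p_value", "log2_fc", "cv", "passes"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample distribution of rank means.

    Ties within a column receive the mean of the rank-means their rank
    range spans, so the procedure is deterministic and idempotent.
    """
    if matrix.scale != "linear":
        raise DataError("quantile normalization expects a linear-scale matrix")
    values = matrix.array()
    n, m = values.shape
    if n == 0 or m == 0:
        return matrix
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(mean_sorted)])

    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        lo = stats.rankdata(col, method="min").astype(int)
        hi = stats.rankdata(col, method="max").astype(int)
        out[:, j] = (cum[hi] - cum[lo - 1]) / (hi - lo + 1)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(frame)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); flips the scale flag to ``"log2"``."""
    if matrix.scale != "linear":
        raise DataError("matrix is already on the log2 scale")
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    if (matrix.array() < 0).any():
        raise DataError("negative values cannot be log-transformed")
    frame = np.log2(matrix.values + pseudocount)
    return matrix.with_values(frame, scale="log2")


def inverse_log2(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform` (used for CV on the linear scale)."""
    if matrix.scale != "log2":
        raise DataError("matrix is not on the log2 scale")
    frame = np.exp2(matrix.values) - pseudocount
    return matrix.with_values(frame.clip(lower=0.0), scale="linear")


def differential_expression(
    matrix: ExpressionMatrix,
    p_threshold: float = 0.001,
    fc_threshold: float = 2.0,
    welch: bool = False,
    bh_correct: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal t-test on log2 values.

    Returns a DataFrame indexed by gene id with columns ``t_statistic``,
    ``p_value``, ``log2_fc`` (tumor minus normal mean), ``cv`` (linear
    scale, all samples), ``passes`` and ``biotype``.

    Parameters
    ----------
    welch
        Use the unequal-variance (Welch) test instead of the pooled
        Student's test.
    bh_correct
        Apply Benjamini-Hochberg correction to the p-values before gating
        (off by default: gating is on raw p-values).
    """
    if matrix.scale != "log2":
        raise DataError("differential expression expects log2-scale values")
    tumor = matrix.samples_in_group("tumor")
    normal = matrix.samples_in_group("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise StatisticalError("each group needs at least 2 samples for a t-test")

    log2v = matrix.values
    a = log2v[tumor].to_numpy(dtype=float)
    b = log2v[normal].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    # constant genes: t is undefined; treat as no evidence (t = 0, p = 1)
    undefined = ~np.isfinite(t_stat)
    t_stat = np.where(undefined, 0.0, t_stat)
    p_val = np.where(undefined, 1.0, p_val)

    log2_fc = a.mean(axis=1) - b.mean(axis=1)

    linear = np.exp2(log2v.to_numpy(dtype=float)) - pseudocount
    linear = np.clip(linear, 0.0, None)
    mean = linear.mean(axis=1)
    sd = linear.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)

    p_gate = p_val
    if bh_correct:
        p_gate = _benjamini_hochberg(p_val)
    passes = (
        (p_gate <= p_threshold)
        & (np.abs(log2_fc) >= np.log2(fc_threshold))
        & (cv > 0)
    )
    table = pd.DataFrame(
        {
            "t_statistic": t_stat,
            "p_value": p_gate if bh_correct else p_val,
            "log2_fc": log2_fc,
            "cv": cv,
            "passes": passes,
        },
        index=matrix.values.index,
    )
    table["biotype"] = [matrix.biotype.get(g, "unannotated") for g in table.index]
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def biotype_partition(
    de_table: pd.DataFrame, biotype: dict[str, str] | None = None
) -> dict[str, list[str]]:
    """Partition the passing genes by biotype.

    Genes absent from the biotype map land in an ``"unannotated"`` bucket
    rather than being dropped.  Empty buckets are omitted.
    """
    passing = de_table.index[de_table["passes"]]
    buckets: dict[str, list[str]] = {}
    for gene in passing:
        if biotype is not None:
            label = biotype.get(gene, "unannotated")
        else:
            label = de_table.at[gene, "biotype"]
        buckets.setdefault(label, []).append(gene)
    return buckets
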