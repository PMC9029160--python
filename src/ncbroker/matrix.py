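"""Expression-matrix container shared by every pipeline stage.

The matrix V holds genes X = [x_1 ... x_N] as rows and samples
Y = [y_1 ... y_M] as columns, together with the per-gene biotype,
the per-sample group (normal / tumor) and, for tumor samples, a
PAM50-style molecular-subtype label.  A scale flag distinguishes
linear (FPKM-like, non-negative) values from log2-transformed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

#: closed biotype vocabulary; anything else is rejected at construction
BIOTYPES = frozenset(
    {
        "protein_coding",
        "pseudogene",
        "antisense",
        "lincRNA",
        "processed_transcript",
        "repeat",
    }
)

NCRNA_BIOTYPES = frozenset(BIOTYPES - {"protein_coding"})

GROUPS = frozenset({"normal", "tumor"})


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with sample/gene metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    biotype
        Mapping gene id -> biotype (one of :data:`BIOTYPES`).
    group
        Mapping sample id -> ``"normal"`` or ``"tumor"``.
    subtype
        Mapping tumor-sample id -> subtype label.  Must cover every
        tumor sample; normal samples carry no subtype.
    scale
        ``"linear"`` for non-negative FPKM-like values, ``"log2"``
        after log transformation.
    """

    values: pd.DataFrame
    biotype: dict[str, str] = field(default_factory=dict)
    group: dict[str, str] = field(default_factory=dict)
    subtype: dict[str, str] = field(default_factory=dict)
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise DataError(f"unknown scale flag: {self.scale!r}")
        if self.values.isna().any().any():
            raise DataError("expression matrix contains missing values")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise DataError("linear-scale matrix contains negative values")
        bad = set(self.biotype.values()) - BIOTYPES
        if bad:
            raise DataError(f"unknown biotypes: {sorted(bad)}")
        bad = set(self.group.values()) - GROUPS
        if bad:
            raise DataError(f"unknown sample groups: {sorted(bad)}")
        missing = [
            s
            for s, g in self.group.items()
            if g == "tumor" and s in self.values.columns and s not in self.subtype
        ]
        if missing:
            raise DataError(f"tumor samples without subtype label: {missing[:5]}")

    # -- identity -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- group access -------------------------------------------------
    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group.get(s) == group]

    def ncrna_ids(self) -> list[str]:
        return [g for g in self.gene_ids if self.biotype.get(g) in NCRNA_BIOTYPES]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Copy of this matrix with new values (metadata shared)."""
        return replace(self, values=values, scale=scale or self.scale)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise DataError(f"genes not in matrix: {missing[:5]}")
        return self.with_values(self.values.loc[gene_ids])

    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)
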