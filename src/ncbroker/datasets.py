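"""Small bundled example tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def bc_subtype_fractions() -> pd.DataFrame:
    """Published subtype-dominance fractions of 13 tumor biclusters.

    A 13 x 4 table of PAM50 subtype fractions (luminal A, luminal B,
    normal-like, basal) for the tumor biclusters of a breast-cancer
    RNA-Seq cohort, as printed (rounded to two decimals, so rows sum to
    0.99-1.00).  Used as the worked example for signature-bicluster
    selection.
    """
    ref = resources.files("ncbroker.data").joinpath("bc_subtype_fractions.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="bicluster")
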