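import numpy as np
import pandas as pd
import pytest

from ncbroker.matrix import ExpressionMatrix


def make_matrix(
    values: np.ndarray,
    scale: str = "log2",
    n_normal: int | None = None,
    biotype: dict | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with simple metadata.

    The first ``n_normal`` columns (default: half) become normal samples,
    the rest tumor with alternating subtype labels.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if n_normal is None:
        n_normal = n_samples // 2
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    group = {
        s: ("normal" if j < n_normal else "tumor") for j, s in enumerate(samples)
    }
    subtypes = ["basal", "luminal_A"]
    subtype = {
        s: subtypes[j % 2]
        for j, s in enumerate(samples)
        if group[s] == "tumor"
    }
    frame = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(
        values=frame,
        biotype=biotype or {g: "protein_coding" for g in genes},
        group=group,
        subtype=subtype,
        scale=scale,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
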