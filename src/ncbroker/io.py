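"""Readers and writers for the pipeline's on-disk formats.

All tabular artifacts are TSV (UTF-8, '.' decimal); networks are
GraphML plus a flat edge-list TSV; bicluster sets and ground truth are
JSON.  Gene and sample identifiers are opaque strings.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .biclustering import Bicluster, BiclusterSet
from .matrix import ExpressionMatrix


# ---------------------------------------------------------------------------
# expression matrix + metadata
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression_matrix.tsv",
        "meta": outdir / "sample_metadata.tsv",
        "biotype": outdir / "gene_biotypes.tsv",
    }
    frame = matrix.values.copy()
    frame.index.name = "gene_id"
    frame.to_csv(paths["matrix"], sep="\t")
    meta = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group": [matrix.group.get(s, "") for s in matrix.sample_ids],
            "subtype": [matrix.subtype.get(s, "") for s in matrix.sample_ids],
        }
    )
    meta.to_csv(paths["meta"], sep="\t", index=False)
    bio = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "biotype": [matrix.biotype.get(g, "") for g in matrix.gene_ids],
        }
    )
    bio.to_csv(paths["biotype"], sep="\t", index=False)
    return paths


def read_expression(
    matrix_path: str | Path,
    meta_path: str | Path,
    biotype_path: str | Path | None = None,
    scale: str = "linear",
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    group = dict(zip(meta["sample_id"], meta["group"]))
    subtype = {
        s: st for s, st in zip(meta["sample_id"], meta["subtype"]) if st
    }
    biotype: dict[str, str] = {}
    if biotype_path is not None:
        bio = pd.read_csv(biotype_path, sep="\t", dtype=str).fillna("")
        biotype = {g: b for g, b in zip(bio["gene_id"], bio["biotype"]) if b}
    return ExpressionMatrix(
        values=values, biotype=biotype, group=group, subtype=subtype, scale=scale
    )


# ---------------------------------------------------------------------------
# biclusters
# ---------------------------------------------------------------------------

def write_biclusters(bset: BiclusterSet, path: str | Path) -> None:
    payload = {
        "gene_thresholds": bset.gene_thresholds,
        "sample_thresholds": bset.sample_thresholds,
        "seed": bset.seed,
        "biclusters": [
            {
                "genes": bc.genes,
                "samples": bc.samples,
                "gene_scores": bc.gene_scores,
                "sample_scores": bc.sample_scores,
                "score": bc.score,
                "thresholds": list(bc.thresholds),
                "robustness": bc.robustness,
                "robustness_ratio": bc.robustness_ratio,
            }
            for bc in bset
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_biclusters(path: str | Path) -> BiclusterSet:
    payload = json.loads(Path(path).read_text())
    biclusters = [
        Bicluster(
            genes=raw["genes"],
            samples=raw["samples"],
            gene_scores=raw["gene_scores"],
            sample_scores=raw["sample_scores"],
            score=raw["score"],
            thresholds=tuple(raw["thresholds"]),
            robustness=raw["robustness"],
            robustness_ratio=raw["robustness_ratio"],
        )
        for raw in payload["biclusters"]
    ]
    return BiclusterSet(
        biclusters,
        payload["gene_thresholds"],
        payload["sample_thresholds"],
        payload["seed"],
    )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


EDGE_COLUMNS = ["source", "target", "mi", "distance", "null_p", "persistence"]


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "mi": d.get("mi"),
            "distance": d.get("distance"),
            "null_p": d.get("null_p"),
            "persistence": d.get("persistence"),
        }
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    frame = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for _, row in frame.iterrows():
        graph.add_edge(
            str(row["source"]),
            str(row["target"]),
            mi=float(row["mi"]),
            distance=float(row["distance"]),
            null_p=float(row["null_p"]),
            persistence=float(row["persistence"]),
        )
    return graph
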