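"""Per-ncRNA "functional context" reports.

Joins the broker ranking, the module landscape, and optional
user-supplied annotation / external-correlation tables into one record
per ranked ncRNA.  Annotation and correlation values are pure
pass-through: nothing is computed from external services and numeric
values are never altered.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import pandas as pd

from .errors import ConfigurationError
from .landscape import ModuleLandscape


@dataclass
class BrokerContext:
    ncrna_id: str
    biotype: str
    normalized_brokerage: float
    interactors: list[str]
    modules: list[tuple[str, float]] = field(default_factory=list)
    annotations: dict[str, list[str]] = field(default_factory=dict)
    external_correlations: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )


def isolated_ncrnas(graph: nx.Graph) -> list[str]:
    """ncRNA nodes with no surviving edges (the report's appendix)."""
    return sorted(
        v
        for v in graph.nodes
        if graph.nodes[v].get("is_ncrna") and graph.degree(v) == 0
    )


def build_contexts(
    graph: nx.Graph,
    landscape: ModuleLandscape | None,
    ranking: list[tuple[str, float, list[str]]],
    annotation_table: pd.DataFrame | None = None,
    correlation_table: pd.DataFrame | None = None,
    min_module_strength: float = 0.1,
) -> list[BrokerContext]:
    """One context per ranked ncRNA, in ranking order.

    ``annotation_table`` needs columns (gene_id, term);
    ``correlation_table`` needs (gene_id, rho, p, adj_p).  Rows that
    reference genes absent from the network trigger a warning but are
    kept for the genes that do match.
    """
    annotations: dict[str, list[str]] = {}
    if annotation_table is not None:
        unknown = set(annotation_table["gene_id"]) - set(graph.nodes)
        if unknown:
            warnings.warn(
                f"annotation table references {len(unknown)} genes not in the network"
            )
        for _, row in annotation_table.iterrows():
            annotations.setdefault(str(row["gene_id"]), []).append(str(row["term"]))

    correlations: dict[str, tuple[float, float, float]] = {}
    if correlation_table is not None:
        unknown = set(correlation_table["gene_id"]) - set(graph.nodes)
        if unknown:
            warnings.warn(
                f"correlation table references {len(unknown)} genes not in the network"
            )
        for _, row in correlation_table.iterrows():
            correlations[str(row["gene_id"])] = (
                float(row["rho"]),
                float(row["p"]),
                float(row["adj_p"]),
            )

    contexts = []
    for ncrna_id, norm_b, interactors in ranking:
        modules: list[tuple[str, float]] = []
        if landscape is not None and ncrna_id in landscape.membership:
            modules = sorted(
                (
                    (m, s)
                    for m, s in landscape.membership[ncrna_id].items()
                    if s >= min_module_strength
                ),
                key=lambda t: (-t[1], t[0]),
            )
        contexts.append(
            BrokerContext(
                ncrna_id=ncrna_id,
                biotype=graph.nodes[ncrna_id].get("biotype", "unannotated"),
                normalized_brokerage=norm_b,
                interactors=list(interactors),
                modules=modules,
                annotations={
                    g: annotations[g] for g in interactors if g in annotations
                },
                external_correlations={
                    g: correlations[g] for g in interactors if g in correlations
                },
            )
        )
    return contexts


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def contexts_to_frame(contexts: list[BrokerContext]) -> pd.DataFrame:
    """Flat TSV-ready view (lists joined with commas, stable field order)."""
    rows = []
    for c in contexts:
        rows.append(
            {
                "ncrna_id": c.ncrna_id,
                "biotype": c.biotype,
                "normalized_brokerage": c.normalized_brokerage,
                "interactors": ",".join(c.interactors),
                "modules": ",".join(f"{m}:{s:.6g}" for m, s in c.modules),
                "annotations": ";".join(
                    f"{g}={'|'.join(terms)}" for g, terms in c.annotations.items()
                ),
                "external_correlations": ";".join(
                    f"{g}={rho:.10g},{p:.10g},{ap:.10g}"
                    for g, (rho, p, ap) in c.external_correlations.items()
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ncrna_id",
            "biotype",
            "normalized_brokerage",
            "interactors",
            "modules",
            "annotations",
            "external_correlations",
        ],
    )


def contexts_to_json(
    contexts: list[BrokerContext], isolated: list[str] | None = None
) -> str:
    payload = {
        "brokers": [asdict(c) for c in contexts],
        "isolated_ncrnas": list(isolated or []),
    }
    return json.dumps(payload, indent=2)


def contexts_from_json(text: str) -> tuple[list[BrokerContext], list[str]]:
    payload = json.loads(text)
    contexts = []
    for raw in payload["brokers"]:
        raw["modules"] = [tuple(m) for m in raw["modules"]]
        raw["external_correlations"] = {
            g: tuple(v) for g, v in raw["external_correlations"].items()
        }
        contexts.append(BrokerContext(**raw))
    return contexts, payload.get("isolated_ncrnas", [])


def contexts_to_markdown(
    contexts: list[BrokerContext], isolated: list[str] | None = None
) -> str:
    lines = ["# ncRNA broker contexts", ""]
    if not contexts:
        lines.append("_No ranked ncRNA brokers._")
    for rank, c in enumerate(contexts, start=1):
        lines.append(f"## {rank}. {c.ncrna_id} ({c.biotype})")
        lines.append("")
        lines.append(f"- normalized brokerage: {c.normalized_brokerage:.4f}")
        lines.append(f"- interactors: {', '.join(c.interactors) or '(none)'}")
        if c.modules:
            mods = ", ".join(f"{m} ({s:.2f})" for m, s in c.modules)
            lines.append(f"- module contexts: {mods}")
        for g in c.interactors:
            if g in c.annotations:
                lines.append(f"  - {g}: {', '.join(c.annotations[g])}")
            if g in c.external_correlations:
                rho, p, ap = c.external_correlations[g]
                lines.append(
                    f"  - {g}: external rho={rho:.4g} (p={p:.3g}, adj={ap:.3g})"
                )
        lines.append("")
    if isolated:
        lines.append("## Isolated ncRNAs (no surviving edges)")
        lines.append("")
        lines.append(", ".join(isolated))
        lines.append("")
    return "\n".join(lines)


def render_report(
    contexts: list[BrokerContext],
    fmt: str = "tsv",
    isolated: list[str] | None = None,
) -> str:
    """Render the broker report as ``tsv``, ``json`` or ``markdown``."""
    if fmt == "tsv":
        return contexts_to_frame(contexts).to_csv(sep="\t", index=False)
    if fmt == "json":
        return contexts_to_json(contexts, isolated)
    if fmt == "markdown":
        return contexts_to_markdown(contexts, isolated)
    raise ConfigurationError(f"unknown report format: {fmt!r}")
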