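"""End-to-end orchestration: simulate/load -> DE -> biclusters -> network
-> topology -> modules -> broker contexts.

One master seed drives everything; each stage derives its own seed from
the master seed and the stage name, so any stage can be reproduced in
isolation.  Every intermediate artifact is written to the run directory
together with a machine-readable manifest carrying the package version,
the derived seeds and a hash of the effective parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .biclustering import (
    filter_biclusters,
    isa_robustness,
    isa_run,
    select_signature_biclusters,
    subtype_fractions,
)
from .context import build_contexts, isolated_ncrnas, render_report
from .errors import ConfigurationError
from .io import (
    read_expression,
    write_biclusters,
    write_edge_list,
    write_expression,
    write_network,
)
from .landscape import ModuleLandscape, module_landscape
from .matrix import ExpressionMatrix, NCRNA_BIOTYPES
from .network import build_template_network
from .prep import differential_expression, log2_transform, quantile_normalize
from .simulate import GroundTruth, SimulationConfig, simulate_expression
from .topology import (
    DisruptionProfile,
    disruption_profile,
    node_topology_table,
    rank_ncrna_brokers,
)

log = logging.getLogger("ncbroker")


@dataclass
class PipelineConfig:
    """Every tunable of the four-step workflow, with paper-scale defaults
    (p <= 0.001, FC >= 2, biclusters of >= 10 genes x 7 samples, 1000
    permutations, 100 bootstrap randomizations)."""

    # input: either the three paths or a simulate block
    matrix_path: str | None = None
    meta_path: str | None = None
    biotype_path: str | None = None
    simulate: SimulationConfig | None = field(
        default_factory=SimulationConfig
    )
    seed: int = 0
    # expression_prep
    pseudocount: float = 1.0
    p_threshold: float = 0.001
    fc_threshold: float = 2.0
    welch: bool = False
    # biclustering
    gene_thresholds: list[float] = field(default_factory=lambda: [1.5, 2.0, 2.5, 3.0])
    sample_thresholds: list[float] = field(default_factory=lambda: [1.0, 1.5, 2.0])
    n_isa_seeds: int = 100
    bicluster_group: str = "tumor"
    n_shuffles: int = 3
    min_genes: int = 10
    min_samples: int = 7
    # shuffled-data fixed points score ~1 by construction while planted
    # modules land at ~1.6-2.3 across cohort sizes; 1.5 splits the two
    # distributions (see docs/methods.md)
    min_robustness: float = 1.5
    robustness_metric: str = "ratio"
    # per-subtype maxima mirror how dominance tables are read in practice
    # (top cells can sit below 0.5); strict majority mode remains available
    selection_mode: str = "top_per_subtype"
    dominance_threshold: float = 0.5
    # coexpression_network
    network_group: str = "tumor"
    metric: str = "mi"
    # with thousands of candidate pairs, 0.01 keeps the expected number of
    # surviving chance edges below one; the library default (0.05) suits
    # single-edge tests
    alpha: float = 0.01
    min_persistence: float = 0.6
    # signed co-expression: drop negatively associated pairs, which on
    # quantile-normalized data are dominated by compositional artifacts
    signed: bool = True
    n_perm: int = 1000
    n_boot: int = 100
    n_bins: int | None = None
    # module_landscape
    damping: float = 0.85
    # topology / disruption
    top_k: int = 5
    n_random_removals: int = 100

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        raw = asdict(self)
        return raw

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.get("simulate")
        if isinstance(sim, dict):
            raw["simulate"] = SimulationConfig(**sim)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def parameter_hash(self) -> str:
        raw = self.to_dict()
        if raw.get("simulate"):
            # the simulate seed is derived from the master seed, so the
            # configured value is not an effective parameter
            raw["simulate"]["seed"] = None
        canonical = json.dumps(raw, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineResult:
    outdir: Path
    matrix: ExpressionMatrix
    truth: GroundTruth | None
    de_table: pd.DataFrame
    bicluster_set: object
    fractions: pd.DataFrame | None
    selected: list[tuple[int, str]]
    network: nx.Graph
    landscape: ModuleLandscape | None
    topology: pd.DataFrame
    ranking: list[tuple[str, float, list[str]]]
    disruption: DisruptionProfile | None
    contexts: list
    manifest: dict


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    annotation_table: pd.DataFrame | None = None,
    correlation_table: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute all stages and write every artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameter_hash": config.parameter_hash(),
        "master_seed": config.seed,
        "stage_seeds": {},
        "artifacts": [],
        "stages": {},
    }

    def _artifact(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(outdir)))

    # -- stage 1: input ----------------------------------------------
    truth: GroundTruth | None = None
    if config.matrix_path:
        if not config.meta_path:
            raise ConfigurationError("meta_path required with matrix_path")
        matrix = read_expression(
            config.matrix_path, config.meta_path, config.biotype_path
        )
    elif config.simulate is not None:
        sim = replace(config.simulate, seed=config.stage_seed("simulate"))
        manifest["stage_seeds"]["simulate"] = sim.seed
        matrix, truth = simulate_expression(sim)
        truth.to_json(outdir / "ground_truth.json")
        _artifact(outdir / "ground_truth.json")
    else:
        raise ConfigurationError("config needs input paths or a simulate block")
    for p in write_expression(matrix, outdir / "expression").values():
        _artifact(p)

    # -- stage 2: expression_prep ------------------------------------
    log.info("normalizing %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    normed = log2_transform(
        quantile_normalize(matrix), pseudocount=config.pseudocount
    )
    de_table = differential_expression(
        normed,
        p_threshold=config.p_threshold,
        fc_threshold=config.fc_threshold,
        welch=config.welch,
        pseudocount=config.pseudocount,
    )
    de_table.to_csv(outdir / "de_table.tsv", sep="\t")
    _artifact(outdir / "de_table.tsv")
    passing = de_table.index[de_table["passes"]].tolist()
    de_genes = [g for g in passing if matrix.biotype.get(g) == "protein_coding"]
    de_ncrnas = [g for g in passing if matrix.biotype.get(g) in NCRNA_BIOTYPES]
    manifest["stages"]["expression_prep"] = {
        "n_passing": len(passing),
        "n_de_genes": len(de_genes),
        "n_de_ncrnas": len(de_ncrnas),
    }
    log.info("%d DE genes, %d DE ncRNAs", len(de_genes), len(de_ncrnas))

    # -- stage 3: biclustering ---------------------------------------
    isa_seed = config.stage_seed("biclustering")
    manifest["stage_seeds"]["biclustering"] = isa_seed
    bic_samples = (
        matrix.samples_in_group(config.bicluster_group)
        if config.bicluster_group
        else matrix.sample_ids
    )
    sub = normed.with_values(normed.values.loc[de_genes, bic_samples]) if de_genes else None
    if sub is not None and de_genes:
        bset = isa_run(
            sub,
            gene_thresholds=config.gene_thresholds,
            sample_thresholds=config.sample_thresholds,
            n_seeds=config.n_isa_seeds,
            seed=isa_seed,
        )
        for bc in bset:
            isa_robustness(
                bc, sub, n_shuffles=config.n_shuffles, seed=isa_seed
            )
        bset = filter_biclusters(
            bset,
            min_genes=config.min_genes,
            min_samples=config.min_samples,
            min_robustness=config.min_robustness,
            metric=config.robustness_metric,
        )
    else:
        from .biclustering import BiclusterSet

        bset = BiclusterSet([], config.gene_thresholds, config.sample_thresholds, isa_seed)
    write_biclusters(bset, outdir / "biclusters.json")
    _artifact(outdir / "biclusters.json")
    manifest["stages"]["biclustering"] = {"n_biclusters": len(bset)}

    fractions = None
    selected: list[tuple[int, str]] = []
    if len(bset):
        fractions = subtype_fractions(bset, matrix.subtype, matrix.group)
        fractions.to_csv(outdir / "subtype_fractions.tsv", sep="\t")
        _artifact(outdir / "subtype_fractions.tsv")
        selected = select_signature_biclusters(
            fractions, mode=config.selection_mode, threshold=config.dominance_threshold
        )
    manifest["stages"]["selection"] = {"selected": [[i, s] for i, s in selected]}

    # -- stage 4: coexpression_network -------------------------------
    sig_genes: list[str] = []
    for idx, _ in selected:
        sig_genes.extend(bset[idx - 1].genes)
    sig_genes = list(dict.fromkeys(sig_genes))
    net_seed = config.stage_seed("network")
    manifest["stage_seeds"]["network"] = net_seed
    log2_fc = de_table["log2_fc"].to_dict()
    # the template network is subtype-specific: restricting to tumor
    # samples keeps edges that reflect co-regulation among tumors rather
    # than the normal-vs-tumor contrast every DE gene shares
    net_samples = (
        matrix.samples_in_group(config.network_group)
        if config.network_group
        else matrix.sample_ids
    )
    net_matrix = normed.with_values(normed.values[net_samples])
    if sig_genes:
        graph = build_template_network(
            net_matrix,
            genes=sig_genes,
            ncrnas=de_ncrnas,
            alpha=config.alpha,
            min_persistence=config.min_persistence,
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            seed=net_seed,
            n_bins=config.n_bins,
            metric=config.metric,
            log2_fc=log2_fc,
            signed=config.signed,
        )
    else:
        log.warning("no signature biclusters selected; network is empty")
        graph = nx.Graph(metric=config.metric.upper())
    write_network(graph, outdir / "network.graphml")
    write_edge_list(graph, outdir / "edges.tsv")
    _artifact(outdir / "network.graphml")
    _artifact(outdir / "edges.tsv")
    manifest["stages"]["network"] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
    }

    # -- stage 5: module_landscape -----------------------------------
    scape: ModuleLandscape | None = None
    if graph.number_of_nodes():
        scape = module_landscape(graph, damping=config.damping, weight="mi")
        scape.membership_frame().to_csv(outdir / "module_membership.tsv", sep="\t")
        _artifact(outdir / "module_membership.tsv")
    manifest["stages"]["modules"] = {
        "n_modules": scape.n_modules if scape else 0
    }

    # -- stage 6: topology + disruption ------------------------------
    topo = node_topology_table(graph) if graph.number_of_nodes() else pd.DataFrame()
    topo.to_csv(outdir / "topology.tsv", sep="\t")
    _artifact(outdir / "topology.tsv")
    ranking = rank_ncrna_brokers(graph) if graph.number_of_nodes() else []
    disruption = None
    targets = [r[0] for r in ranking[: config.top_k]]
    if targets:
        disruption = disruption_profile(
            graph,
            targets,
            n_random=config.n_random_removals,
            seed=config.stage_seed("disruption"),
        )
        disruption.to_frame().to_csv(outdir / "disruption.tsv", sep="\t")
        _artifact(outdir / "disruption.tsv")
    manifest["stage_seeds"]["disruption"] = config.stage_seed("disruption")

    # -- stage 7: context_summary ------------------------------------
    contexts = build_contexts(
        graph, scape, ranking, annotation_table, correlation_table
    )
    isolated = isolated_ncrnas(graph)
    for fmt, suffix in (("tsv", "tsv"), ("json", "json"), ("markdown", "md")):
        path = outdir / f"broker_contexts.{suffix}"
        path.write_text(render_report(contexts, fmt, isolated))
        _artifact(path)
    manifest["stages"]["contexts"] = {
        "n_brokers": len(contexts),
        "n_isolated": len(isolated),
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        outdir=outdir,
        matrix=matrix,
        truth=truth,
        de_table=de_table,
        bicluster_set=bset,
        fractions=fractions,
        selected=selected,
        network=graph,
        landscape=scape,
        topology=topo,
        ranking=ranking,
        disruption=disruption,
        contexts=contexts,
        manifest=manifest,
    )
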