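"""Synthetic expression cohorts and benchmark graphs with known ground truth.

The generator emulates a two-group (normal / tumor) RNA-Seq cohort with
subtype-structured tumor samples, implanted differentially expressed gene
blocks (biclusters), ncRNAs co-expressed with specific gene modules, and
"broker" ncRNAs that load on the latent factors of two or more modules and
therefore bridge them in a co-expression network.  Every planted structure
is returned as :class:`GroundTruth` so downstream stages can be benchmarked
without any external download.

Generative model (all on the log2 scale; the returned matrix is linear):

* background: log2 values i.i.d. Gaussian with mean ``background_log2_mean``
  and standard deviation ``noise_sd`` (an FPKM-like log-normal marginal);
* module co-expression: each planted bicluster k owns a per-sample latent
  factor f_k ~ N(0, 1); member genes add ``latent_loading * noise_sd * f_k``;
* differential expression: planted DE rows add ``effect_size * noise_sd``
  to every tumor column;
* bicluster block: member genes add a further ``effect_size * noise_sd``
  restricted to the bicluster's sample subset, drawn from one dominant
  subtype with a small contamination fraction;
* broker ncRNAs load equally on the latent factors of >= 2 modules with
  a per-factor loading of ``broker_loading * noise_sd``, so each bridge
  carries co-expression comparable to within-module gene pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import ExpressionMatrix

#: default subtype mix of the tumor samples
DEFAULT_SUBTYPE_PROPORTIONS = {
    "luminal_A": 0.35,
    "luminal_B": 0.25,
    "normal_like": 0.15,
    "basal": 0.25,
}

#: default ncRNA biotype mix (pseudogene-dominated, as in BC cohorts)
DEFAULT_NCRNA_BIOTYPE_PROPORTIONS = {
    "pseudogene": 0.644,
    "antisense": 0.160,
    "lincRNA": 0.114,
    "processed_transcript": 0.031,
    "repeat": 0.051,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the mean shift in units of ``noise_sd`` on the log2
    scale, applied both tumor-wide to planted DE rows and block-wise to
    implanted biclusters.
    """

    n_genes: int = 1000
    n_ncrna: int = 50
    n_normal: int = 106
    n_tumor: int = 124
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS)
    )
    n_biclusters: int = 3
    bicluster_gene_sizes: list[int] = field(default_factory=lambda: [20, 20, 20])
    bicluster_sample_sizes: list[int] = field(default_factory=lambda: [10, 10, 10])
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_brokers: int = 2
    seed: int = 0
    # secondary knobs ------------------------------------------------
    contamination: float = 0.1
    latent_loading: float = 1.2
    broker_loading: float = 1.2
    broker_noise: float = 0.5
    n_background_de: int = 100
    n_module_ncrna: int | None = None  # default: one per module
    n_de_ncrna: int = 10
    ncrna_biotype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NCRNA_BIOTYPE_PROPORTIONS)
    )
    background_log2_mean: float = 5.0

    def validate(self) -> None:
        if min(self.n_genes, self.n_ncrna, self.n_normal, self.n_tumor) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"subtype_proportions sum to {total}, expected 1"
            )
        if len(self.bicluster_gene_sizes) != self.n_biclusters:
            raise ConfigurationError(
                "bicluster_gene_sizes length does not match n_biclusters"
            )
        if len(self.bicluster_sample_sizes) != self.n_biclusters:
            raise ConfigurationError(
                "bicluster_sample_sizes length does not match n_biclusters"
            )
        if any(s < 1 for s in self.bicluster_gene_sizes):
            raise ConfigurationError("every bicluster gene size must be >= 1")
        if sum(self.bicluster_gene_sizes) > self.n_genes:
            raise ConfigurationError("bicluster gene sizes exceed n_genes")
        if any(s > self.n_tumor for s in self.bicluster_sample_sizes):
            raise ConfigurationError("a bicluster sample size exceeds n_tumor")
        if sum(self.bicluster_gene_sizes) + self.n_background_de > self.n_genes:
            raise ConfigurationError(
                "bicluster gene sizes plus n_background_de exceed n_genes"
            )
        if self.n_brokers > self.n_ncrna:
            raise ConfigurationError("n_brokers exceeds n_ncrna")
        if self.n_brokers > 0 and self.n_biclusters < 2:
            raise ConfigurationError(
                "brokers bridge >= 2 modules; need n_biclusters >= 2"
            )
        if not 0 <= self.contamination < 1:
            raise ConfigurationError("contamination must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    de_gene_ids: set[str]
    bicluster_memberships: list[tuple[set[str], set[str], str]]
    broker_ids: set[str]
    module_assignments: dict[str, int]
    broker_modules: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_gene_ids": sorted(self.de_gene_ids),
            "bicluster_memberships": [
                {"genes": sorted(g), "samples": sorted(s), "dominant_subtype": d}
                for g, s, d in self.bicluster_memberships
            ],
            "broker_ids": sorted(self.broker_ids),
            "module_assignments": self.module_assignments,
            "broker_modules": self.broker_modules,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _draw_labels(rng: np.random.Generator, n: int, proportions: dict[str, float]) -> list[str]:
    labels = sorted(proportions)
    p = np.array([proportions[k] for k in labels], dtype=float)
    p = p / p.sum()
    return [str(x) for x in rng.choice(labels, size=n, p=p)]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a linear-scale expression matrix plus its ground truth.

    Deterministic given ``config.seed``; all randomness flows through one
    :class:`numpy.random.Generator`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    ncrna_ids = [f"NC{i:04d}" for i in range(config.n_ncrna)]
    all_ids = gene_ids + ncrna_ids
    normal_ids = [f"N{i:03d}" for i in range(config.n_normal)]
    tumor_ids = [f"T{i:03d}" for i in range(config.n_tumor)]
    sample_ids = normal_ids + tumor_ids
    n_rows, n_cols = len(all_ids), len(sample_ids)

    group = {s: "normal" for s in normal_ids}
    group.update({s: "tumor" for s in tumor_ids})
    subtype = dict(
        zip(tumor_ids, _draw_labels(rng, config.n_tumor, config.subtype_proportions))
    )
    biotype = {g: "protein_coding" for g in gene_ids}
    biotype.update(
        zip(
            ncrna_ids,
            _draw_labels(rng, config.n_ncrna, config.ncrna_biotype_proportions),
        )
    )

    shift = config.effect_size * config.noise_sd
    log2 = rng.normal(config.background_log2_mean, config.noise_sd, (n_rows, n_cols))
    tumor_cols = np.arange(config.n_normal, n_cols)

    # latent module factors over every sample
    factors = rng.normal(0.0, 1.0, (config.n_biclusters, n_cols))
    loading = config.latent_loading * config.noise_sd

    subtype_labels = sorted(config.subtype_proportions)
    memberships: list[tuple[set[str], set[str], str]] = []
    module_assignments: dict[str, int] = {}
    de_ids: set[str] = set()

    row_of = {gid: i for i, gid in enumerate(all_ids)}
    col_of = {sid: j for j, sid in enumerate(sample_ids)}

    cursor = 0
    for k in range(config.n_biclusters):
        size_g = config.bicluster_gene_sizes[k]
        size_s = config.bicluster_sample_sizes[k]
        genes_k = gene_ids[cursor : cursor + size_g]
        cursor += size_g
        dominant = subtype_labels[k % len(subtype_labels)]

        dom_pool = [s for s in tumor_ids if subtype[s] == dominant]
        other_pool = [s for s in tumor_ids if subtype[s] != dominant]
        n_contam = int(round(config.contamination * size_s))
        n_dom = size_s - n_contam
        if n_dom > len(dom_pool):  # sparse subtype: fill from the rest
            n_dom = len(dom_pool)
            n_contam = size_s - n_dom
        samples_k = list(rng.choice(dom_pool, size=n_dom, replace=False))
        if n_contam:
            samples_k += list(rng.choice(other_pool, size=n_contam, replace=False))

        rows = [row_of[g] for g in genes_k]
        cols = [col_of[s] for s in samples_k]
        log2[np.ix_(rows, tumor_cols)] += shift  # tumor-wide DE signal
        log2[np.ix_(rows, cols)] += shift  # subtype block on top
        log2[rows, :] += loading * factors[k]  # module co-expression

        memberships.append((set(genes_k), set(samples_k), dominant))
        module_assignments.update({g: k for g in genes_k})
        de_ids.update(genes_k)

    # background DE genes: tumor-wide shift, no module or block structure,
    # so the DEG list is (realistically) much larger than any one module
    bg_de = gene_ids[cursor : cursor + config.n_background_de]
    if bg_de:
        rows = [row_of[g] for g in bg_de]
        log2[np.ix_(rows, tumor_cols)] += shift
        de_ids.update(bg_de)

    # ncRNA layers: brokers, single-module ncRNAs, DE-only ncRNAs
    broker_ids: set[str] = set()
    broker_modules: dict[str, list[int]] = {}
    n_module_nc = (
        config.n_biclusters if config.n_module_ncrna is None else config.n_module_ncrna
    )
    block_cols = [
        [col_of[s] for s in samples_k] for _, samples_k, _ in memberships
    ]
    nc_cursor = 0
    for b in range(config.n_brokers):
        nc = ncrna_ids[nc_cursor]
        nc_cursor += 1
        k1 = b % config.n_biclusters
        k2 = (b + 1) % config.n_biclusters
        row = row_of[nc]
        # per-factor loading comparable to module genes, reduced intrinsic
        # noise, and co-activation with both bridged subtype blocks, so
        # each bridge is as tight as within-module co-expression
        b_loading = config.broker_loading * config.noise_sd
        mean = config.background_log2_mean
        log2[row, :] = mean + config.broker_noise * (log2[row, :] - mean)
        log2[row, :] += b_loading * (factors[k1] + factors[k2])
        log2[row, tumor_cols] += shift
        log2[row, block_cols[k1]] += shift
        log2[row, block_cols[k2]] += shift
        broker_ids.add(nc)
        broker_modules[nc] = [k1, k2]
        de_ids.add(nc)
    for j in range(min(n_module_nc, config.n_ncrna - nc_cursor)):
        nc = ncrna_ids[nc_cursor]
        nc_cursor += 1
        k = j % max(config.n_biclusters, 1)
        if config.n_biclusters:
            log2[row_of[nc], :] += loading * factors[k]
            log2[row_of[nc], block_cols[k]] += shift
            module_assignments[nc] = k
        log2[row_of[nc], tumor_cols] += shift
        de_ids.add(nc)
    for _ in range(min(config.n_de_ncrna, config.n_ncrna - nc_cursor)):
        nc = ncrna_ids[nc_cursor]
        nc_cursor += 1
        log2[row_of[nc], tumor_cols] += shift
        de_ids.add(nc)

    if config.effect_size == 0:
        de_ids = set()  # no shift was actually applied

    values = pd.DataFrame(
        np.exp2(log2), index=all_ids, columns=sample_ids, dtype=float
    )
    matrix = ExpressionMatrix(
        values=values, biotype=biotype, group=group, subtype=subtype, scale="linear"
    )
    truth = GroundTruth(
        de_gene_ids=de_ids,
        bicluster_memberships=memberships,
        broker_ids=broker_ids,
        module_assignments=module_assignments,
        broker_modules=broker_modules,
    )
    return matrix, truth


def generate_broker_graph(
    n_cliques: int,
    clique_size: int,
    n_bridges: int,
    seed: int = 0,
    attachments: int = 2,
    require_connected: bool = True,
) -> tuple[nx.Graph, list[str]]:
    """Disjoint cliques joined only through designated bridge nodes.

    Each bridge node attaches to ``attachments`` distinct members of each
    of the two cliques it joins, so bridges are the only inter-clique
    routes and carry maximal brokerage.  Returns the graph and the
    bridge-node labels (the ground-truth brokers).
    """
    if n_cliques < 1 or clique_size < 2:
        raise ConfigurationError("need n_cliques >= 1 and clique_size >= 2")
    if n_bridges < 0:
        raise ConfigurationError("n_bridges must be non-negative")
    if require_connected and n_bridges < n_cliques - 1:
        raise ConfigurationError(
            f"{n_bridges} bridges cannot connect {n_cliques} cliques"
        )
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    cliques: list[list[str]] = []
    for k in range(n_cliques):
        members = [f"C{k}_{i}" for i in range(clique_size)]
        cliques.append(members)
        graph.add_nodes_from(members, role="clique", clique=k)
        graph.add_edges_from(
            (members[a], members[b])
            for a in range(clique_size)
            for b in range(a + 1, clique_size)
        )

    m = min(attachments, clique_size)
    bridge_ids: list[str] = []
    for j in range(n_bridges):
        bridge = f"B{j}"
        bridge_ids.append(bridge)
        graph.add_node(bridge, role="bridge")
        if j < n_cliques - 1:
            pair = (j, j + 1)
        else:  # extra bridges join a random distinct clique pair
            pair = tuple(rng.choice(n_cliques, size=2, replace=False))
        for k in pair:
            targets = rng.choice(cliques[k], size=m, replace=False)
            graph.add_edges_from((bridge, t) for t in targets)
    return graph, bridge_ids
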