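# ncbroker

**ncRNA brokers in cancer-subtype co-expression networks.**

Most non-coding RNAs (ncRNAs) — pseudogenes, antisense transcripts,
lincRNAs — are detected readily by RNA-Seq but remain hard to
*functionalize*. `ncbroker` implements a network-driven inference
pipeline for prioritizing ncRNAs by their topological role in
subtype-specific co-expression networks: an ncRNA that *brokers*
between otherwise-disconnected gene modules is a candidate regulator
whose removal measurably disrupts the network. The pipeline targets
tumor cohorts with molecular subtype labels (e.g. PAM50-classified
breast cancer) but is agnostic to the disease.

The chain:

1. **Differential expression** — quantile + log2 normalization, then a
   tumor-vs-normal t-test gated at `p ≤ 0.001` and fold change ≥ 2.
2. **ISA biclustering** — the Iterative Signature Algorithm finds
   gene-set × sample-set biclusters `B = (I, J)` in the DE submatrix;
   size (≥10 genes × ≥7 samples) and shuffled-data robustness filters,
   then subtype-dominance selection picks the signature biclusters.
3. **Template network** — normalized mutual information (MI) between
   signature genes and DE ncRNAs, edge distance `d = 1 − MI`,
   permutation significance and resampling persistence; ncRNAs are
   embedded into the gene co-expression graph.
4. **Brokerage & disruption** — per node `i`, local efficiency `E_i`
   over the neighbor-induced subgraph (node excluded) gives the
   brokerage

   `B_i = k_i − (k_i − 1) · E_i  ∈ [1, k_i]`,

   maximal when removing `i` disconnects all its neighbors. ncRNAs are
   ranked by network-normalized brokerage, overlapping modules from an
   influence landscape provide their functional contexts, and targeted
   broker removal is compared against a degree-matched random baseline
   via the giant-component fraction.

A synthetic-cohort generator with full ground truth (implanted DE genes,
subtype-dominant biclusters, module-bridging broker ncRNAs) makes every
stage testable end-to-end without any external download.

## Worked example

```python
from ncbroker import bc_subtype_fractions, select_signature_biclusters

table = bc_subtype_fractions()          # bundled 13 x 4 dominance table
print(select_signature_biclusters(table, mode="top_per_subtype"))
print(select_signature_biclusters(table, mode="strict", threshold=0.5))
```

```
[(12, 'luminal_A'), (6, 'luminal_B'), (13, 'normal_like'), (1, 'basal')]
[(1, 'basal'), (13, 'normal_like')]
```

Per subtype, the bicluster maximizing that subtype's sample fraction
(luminal A 0.29, luminal B 0.46, normal-like 0.57, basal 0.73); under a
strict >50% majority only the basal (#1) and normal-like (#13)
biclusters qualify.

End-to-end on a synthetic cohort (106 normal + 124 tumor samples, three
planted 20-gene modules, two planted broker ncRNAs):

```python
from ncbroker.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1), "run1")
print(sorted(res.truth.broker_ids))
print([(ncrna, round(b, 2)) for ncrna, b, _ in res.ranking[:5]])
print(res.disruption.to_frame()[["removed_id", "giant_fraction",
                                 "baseline_p5"]].head(2))
```

```
['NC0000', 'NC0001']
[('NC0000', 0.97), ('NC0001', 0.74), ('NC0004', 0.61), ('NC0003', 0.34), ('NC0002', 0.02)]
     removed_id  giant_fraction  baseline_p5
step
1        NC0000          0.6250      0.81250
2        NC0001          0.3125      0.53125
```

Both planted brokers top the brokerage ranking, and removing them
collapses the giant component to 31% of the network — well below the
5th percentile (53%) of degree-matched random removals. The run
directory contains every intermediate artifact (DE table, bicluster
JSON, GraphML network, edge list, module memberships, topology table,
disruption profile, broker context reports) plus a manifest with seeds
and a parameter hash.

The same workflow is available from the shell:

```bash
ncbroker run --outdir run1 --seed 1
ncbroker simulate --outdir sim --seed 7
ncbroker de --matrix sim/expression_matrix.tsv --meta sim/sample_metadata.tsv \
            --biotype sim/gene_biotypes.tsv --out de.tsv
```

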