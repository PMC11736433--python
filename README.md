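# enetkit

Per-gene **enhancer network** analysis from single-cell chromatin
accessibility: network construction, topology (modules and hubs),
condition comparison, and developmental dynamics.

Genes are rarely controlled by one enhancer. Clusters of enhancers act
together, and single-cell ATAC-seq makes their joint behaviour observable:
two enhancers that open and close in the same cells (high
*co-accessibility*) are likely to cooperate. `enetkit` turns that signal
into a graph per gene — nodes are enhancers correlated with the gene's
expression within ±100 kb of its TSS, edges are enhancer pairs whose
co-accessibility exceeds a threshold (predicted enhancer interactions,
PEIs) — and then asks three questions:

1. **Topology.** Are the networks modular? Louvain communities define
   modules; enhancer pairs split into *Intra* (same module) and *Inter*
   (different modules). Degree-based network/module hubs and betweenness
   identify the load-bearing enhancers.
2. **Comparison.** What changes between two conditions (disease vs
   healthy)? For conditions *n* with adjacency `C[n]` of co-accessibility,
   the difference matrix `d_ij = |(c_ij[2])² − (c_ij[1])²|` (or its
   multi-condition generalization) is converted to a topological-overlap
   dissimilarity

   `t_ij = 1 − (Σ_k d_ik·d_kj + d_ij) / (min(Σ_k d_ik, Σ_k d_kj) + 1 − d_ij)`

   and clustered (average linkage, fixed cut height 0.99) into *altered
   components* — groups of enhancers whose interactions change together.
   A per-gene **network change score** `Σ c_ij[2] − Σ c_ij[1]` over altered
   in-network pairs ranks genes; the top/bottom deciles of connectivity
   change are *Gained*/*Lost* networks.
3. **Dynamics.** Over a stage series, the same machinery yields a
   **network dynamic score** (the standard deviation of the altered-pair
   co-accessibility sum across stages) and *Early/Middle/Late/Unchanged*
   patterns.

Two orthogonal validation layers are included: an eQTL **synergy test** —
for a variant pair (X₁, X₂) in two different enhancers,
`Y ~ β₀ + β₁X₁X₂ + β₂X₁ + β₃X₂ + covariates` is compared with the additive
model by AIC and the interaction p-value calls *synergistic variant pairs*
(SVP, p < 0.01) and *synergistic enhancer pairs* (SEP, ≥ 1 SVP) — and a
paired-sgRNA **CRISPRi screen scorer** (depletion z-scores, single/double
depletion, interaction scores as the negative deviation from a per-query
linear fit). Inter-module enhancer pairs are the ones expected to act
synergistically; intra-module pairs additively.

A seeded synthetic-data module generates every input with planted ground
truth (module blocks, condition-specific edge gains, genotype–genotype
interaction effects, CRISPRi synergy), so the whole pipeline is testable
without external accessions.

## Worked example: the BLK enhancer network

The *BLK* locus (a B-cell receptor signalling kinase) is regulated by a
14-enhancer network arranged in two modules. Seven enhancers carry eQTLs —
two in one module, five in the other, 16 variants in all. Running the
pair-enumeration and SVP/SEP-calling path on that layout:

```python
from enetkit import enumerate_variant_pairs, call_svp_sep

layout = {"E1": (0, 1), "E6": (0, 4), "E7": (1, 1), "E9": (1, 1),
          "E12": (1, 3), "E13": (1, 3), "E14": (1, 3)}  # module, #eQTLs
mapped, module_of = {}, {}
for enh, (mod, k) in layout.items():
    module_of[enh] = mod
    for i in range(k):
        mapped[f"{enh}_v{i}"] = enh
pairs = enumerate_variant_pairs(mapped, module_of)
print(len(pairs), sum(p[4] == "Inter" for p in pairs), sum(p[4] == "Intra" for p in pairs))
```

prints `105 55 50`: the 16 variants form 105 cross-enhancer combinations
(same-enhancer pairs are excluded — perturbing one enhancer twice says
nothing about pair synergy), 55 Inter and 50 Intra. With the observed
interaction tests (7 significant Inter pairs, 1 Intra), `call_svp_sep`
yields SVP rates of **12.7 %** (Inter) vs **2.0 %** (Intra) and SEP rates
of **40.0 %** (4/10 Inter enhancer pairs) vs **9.1 %** (1/11 Intra) — the
synergy signal concentrates in the spatially separated inter-module pairs,
at a fold enrichment of 1.67 over the overall SVP rate.

## Command line

A thin `enet` CLI wires the library into workflows:

```bash
enet simulate --preset disease --outdir sim --seed 1
enet build    --peaks sim/peaks.bed ... --outdir run     # networks + co-accessibility
enet topology --edges run/network_edges.tsv --nodes run/network_nodes.tsv --outdir topo
enet diff     --edges ... --healthy run/coaccessibility_healthy.tsv \
              --disease run/coaccessibility_disease.tsv --outdir diff
enet dynamics / synergy / crispri / enrich ...
```

Every run writes TSV outputs plus a JSON manifest (version, parameters,
config hash); all randomness flows from `--seed`.

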