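# Methods

This note documents the models implemented in `enetkit`, the parameter
defaults and why they hold, the design of the synthetic benchmarks, and
the numerical choices a maintainer would want to know.

## Network construction

**Metacells.** Single-cell ATAC data are too sparse for stable pairwise
statistics, so cells are aggregated: TF-IDF on binarized counts, truncated
SVD (`n_dims = 30`, the usual LSI embedding), then greedy grouping — in a
seeded random order each unassigned cell claims its `k−1` nearest
unassigned neighbours and the group's counts are summed. `k = 50` by
default (`k = 1` is the identity and appropriate when cells are deep
enough to use directly, as in the synthetic benchmarks). Aggregation never
crosses condition boundaries when condition-specific networks are built.

**Co-accessibility.** Default backend: Pearson correlation between peak
columns across metacells, computed only for pairs within `max_dist =
250 kb` (midpoint distance; 250 kb covers the 200 kb maximal span of a
±100 kb gene window). Zero-variance peaks score 0 rather than NaN so that
downstream sums stay total. The alternative `glasso` backend estimates
sparse partial correlations per overlapping 500 kb genomic window with an
elementwise penalty `ρ_ij = base_penalty·(1 + dist_ij/max_dist)`
(`base_penalty = 0.1`), i.e. distant pairs are shrunk harder; pairs scored
in several windows take the mean. The matrix-penalty graphical lasso is a
block coordinate descent over columns (each column update is a lasso
solved by cyclic coordinate descent); with a uniform penalty it reproduces
scikit-learn's scalar implementation to ~1e-4, which the test suite uses
as an independent cross-check. On non-convergence a window falls back to
plain correlation and logs the fact.

**Enhancer–gene links.** Candidates are peaks overlapping TSS ± 100 kb
(BED-convention half-open overlap). Pearson r between peak accessibility
and gene expression across shared metacells is tested by metacell
permutation (`n_shuffle = 100`, one-sided for r > 0 since only positively
correlated enhancers become nodes), BH-corrected within the gene; links
need `r > 0.1` and `FDR < 0.05`. Edges are pairs with co-accessibility
strictly above `pei_threshold = 0.2` — the same boundary used to call
co-accessibility "high" elsewhere in the field. Single-enhancer genes
yield trivial but valid size-1 networks. Condition-specific networks share
one node set (links computed from pooled cells) and differ only in edges.

## Topology

Modules are Louvain communities (networkx implementation, weighted,
`resolution = 1`, seed fixed at 7, node order canonicalized by peak id —
the partition is deterministic). A network is *modular* iff ≥ 2 modules
have ≥ 2 members; pair classification (Intra/Inter) drops nodes in
singleton modules. Network connectivity — the "network score" used for
ranking and comparison — is the mean degree `2E/N` (an `E/N` variant is
available); it is isolated behind one function so an alternative
definition cannot leak into other modules. Normalized degree is
`degree/(N−1)` with N the network (or module) size, so the maximum is 1;
hub selection takes the genome-wide top K (default 5000) or, when K < 1,
the top fraction — the top decile mirrors the intended scale. Betweenness
is the standard shortest-path centrality on the unweighted graph,
normalized by `(N−1)(N−2)/2`. TF-binding similarity is the cosine of
binary enhancer×TF vectors; pairwise mutual information is the plug-in
estimate on the 2×2 table of binarized accessibility, in bits.

## Differential / dynamic module detection

Step 1 builds per-condition adjacencies over one fixed enhancer ordering;
pairs outside the distance window are undefined in the map and enter all
sums as 0, the unique neutral element. Step 2:

* two conditions: `d_ij = |(c_ij[2])² − (c_ij[1])²|` — sign-blind by
  construction (a correlation flipping −0.4 → +0.4 counts as no change);
* n ≥ 3 conditions: `d_ij = sqrt( mean_n |(c_ij[n])² − (c_ij[0])²| )`
  with `c[0]` the across-condition mean. Both keep `0 ≤ d ≤ 1` whenever
  `|c| ≤ 1`.

Step 3 is the topological-overlap dissimilarity (formula in the README).
The index convention is the standard one: the numerator product sum runs
over `k ∉ {i, j}`, row sums exclude only the diagonal; `t_ii = 0`.
Step 4 clusters T by average-linkage hierarchical clustering and cuts the
tree at a fixed height (default **0.99**); `fcluster(criterion="distance")`
keeps merges at height ≤ the cut (boundary inclusive). Clusters below
`min_size = 3` go to the unclustered pool. T is clustered directly; a
`tom_power` hook exists for soft-thresholding variants but defaults to 1.

A network is *differential/dynamic* iff ≥ 2 of its nodes fall in altered
clusters (so at least one altered pair exists). The change score sums raw
`c_ij` (which may be negative) over altered in-network pairs —
disease minus healthy; a clip-at-zero option exists but is off, since
Step 1 imposes no clipping. The dynamic score is the sample standard
deviation (ddof = 1) of the per-stage altered-pair sums. Gained/Lost are
the strict top/bottom `q = 10 %` by rank of the per-gene score difference,
ties broken by gene id (so ⌊qG⌋ each, deterministically); stage patterns
average per-stage network scores within Early/Middle/Late groups and take
the argmax (ties to the earliest group), with non-dynamic networks labeled
Unchanged regardless of scores.

## Synergy (eQTL interaction) analysis

Gene-associated variants are kept only if they fall inside a network
enhancer of that gene. Variant pairs are enumerated *across* enhancers
only: same-enhancer pairs measure one perturbation twice and are excluded
(this exclusion is also what the worked-example arithmetic requires:
16 variants, 105 — not 120 — pairs). Both the synergistic and the
additive model are ordinary least squares on the identical complete-case
sample set; missing dosages are handled per pair by complete-case
analysis. The interaction p-value is the two-sided t-test on β₁, AICs come
from the Gaussian likelihood, and a pair is skipped (reason recorded)
when a genotype is monomorphic after filtering or cases are too few.
SVP: `p < alpha` with `alpha = 0.01` (0.05 is the documented fallback for
sparse cohorts); SEP: ≥ 1 SVP among the enhancer pair's variant pairs.
Fold enrichment per group is `(svp_g/pairs_g)/(svp_all/pairs_all)` with a
two-sided binomial test against the overall rate; the Random reference
permutes the Inter/Intra labels (seeded) and centres on fold 1.
Covariates (expression factors, genotype PCs, platform, sex) are consumed
as a supplied matrix — estimating them is outside this package's scope.
A minor-allele-count filter is available (`min_mac`, default off).

## CRISPRi pair scoring

Libraries are scaled to equal totals first (raw-count ratios would
confound depletion with sequencing depth; toggleable), pairs with raw
day-0 reads < 30 are dropped, and the depletion
`e = log2((c30+10)/(c0+10))` is z-normalized by the mean/sd of
control–control pairs. Single depletion of guide K: mean z over
(K, control) pairs in both orientations. Double depletion: mean over the
two orientations of a pair. For each query guide, double depletion is
regressed linearly on the partners' single depletion; the interaction
score is the *negative* residual (extra depletion ⇒ positive synergy),
z-normalized against the query's control partners, and the two query
perspectives of a pair are averaged. Enhancer-pair scores average the
pairs whose guides both rank in the most-depleting half of their
enhancer's guides ("top 50 %" read as strongest perturbation — the
reading that selects effective guides). Note a property of the linear-fit
baseline: when many partners of a query are synergistic, the fitted line
centres between the additive and synergistic clouds, so additive pairs
score negative rather than 0; the inter-vs-intra *contrast* is the robust
readout, and an additive screen scores ≈ 0 throughout.

## Interval enrichment

The recurring statistic is `(m/n)/(M/N)` with a two-sided binomial test of
m hits in n loci at rate M/N (capped at 1); m may exceed n since a locus
can host several SNPs. Backgrounds re-place every open-chromatin region
uniformly at random on its own chromosome, length preserved, overlaps
among shuffled intervals permitted, optional exclusion regions honoured by
rejection sampling; `n_shuffles` concatenates replicates for averaging
(default 1). Ranked-gene enrichment slides a window (default 100) by 1
along a ranking and reports the in-window target rate over the
genome-wide rate.

## Synthetic data: what it emulates, and what it does not

The generator parameterizes exactly the statistics the analyses consume.
Accessibility is binary with latent per-cell module activities
(`p_active = 0.5`): a peak opens with probability 0.999 when its module is
active and 0.001 otherwise, giving within-module co-accessibility ≈ 0.996
and cross-module ≈ 0. Expression is `0.8 ×` the sum of module activities
plus unit Gaussian noise, shifted to be non-negative. A module's TFs are a
random 8-of-30 subset bound at rate 0.85 over a 0.05 background, so
intra-module pairs share binding profiles. Planted disease structure
couples a designated 6-peak block to one shared driver only in the
disease condition, with the coupling weight chosen so the pairwise
co-accessibility jump is `gained_delta = 0.5`; stage series couple each
dynamic gene's block only in its assigned stage group. Genotypes are
Hardy–Weinberg at MAF 0.3; expression follows the interactive model with
main effects 0.3, covariate effects ~N(0, 0.5), noise sd 1, and
interaction β₁ planted on inter-module variant pairs only. CRISPRi counts
are negative-binomial at day 0 (mean 2000) scaled by
`2^(guide effects + δ)` with δ = −2 on inter-module pairs in the synergy
screen; 12 guides per enhancer and 16 controls so that enhancer-pair
averages and single-depletion estimates cover
enough guide pairs for a tight additive null.

**Cohort sizing and the fixed cut — a variance analysis.** The 0.99 cut
on T tolerates roughly `d < 0.01` on unchanged pairs (since
`t ≈ 1 − d` when row sums are small). For a stable pair with
co-accessibility c estimated from n cells per condition,
`sd(d) ≈ 2√2·c·sd(ĉ)`, and the margin must hold simultaneously for every
stable pair in the peak universe (hundreds of pairs), i.e. at ~6 sd. The
near-deterministic coupling (error rate 0.001) and the 12 000-cell
condition cohorts used in the comparison benchmarks satisfy this; with
moderate coupling (say r ≈ 0.6) or few thousand cells, estimation jitter
of *unchanged* strong pairs exceeds the cut tolerance and stable modules
surface as false altered components. This is a real sensitivity of the
fixed-cut procedure, not of the implementation: on noisier data, raise
`min_size`, lower `cut_height`, or pre-filter by effect size.

Accordingly, passing benchmarks show that the formulas, the clustering
and the scores do what they claim under their stated assumptions; they do
not show robustness to count-level scATAC noise, batch structure, doublets
or peak-calling artifacts, which the generator deliberately omits.

## Problem sizes used by the shipped benchmarks

Simulated studies run at: 30 genes × two 4-peak modules (plus 6-peak
gained blocks in 3 genes) × 12 000 cells per condition for the
condition-comparison study; 2 000 cells for module-structure and linking
benchmarks; 1000/200 replicates for the interaction test's type-I/power
characterization (n = 500 samples, MAF 0.3); a 7-enhancer, 100-guide
paired screen for CRISPRi. These sizes are the package's documented study
conditions and complete in about a minute on one CPU.

## Known limitations

* Cicero's exact numerical output is not reproduced; the correlation
  backend is a transparent stand-in whose values feed the same formulas.
* The fixed 0.99 cut is sensitive to adjacency estimation noise (see the
  variance analysis above).
* The synergy analysis consumes pre-computed eQTLs and covariates; it does
  not discover associations, prune LD, or estimate expression factors.
* Enhancer networks are correlation-based: no causal direction, no 3D
  contact information.
* `classify_gained_lost` uses strict rank deciles; with many tied scores
  the tie-break (by gene id) is deterministic but arbitrary, and is logged.
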