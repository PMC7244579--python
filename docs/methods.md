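# Methods

This note records the statistical model behind each stage, the default
parameters and why they hold, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Rank–rank hypergeometric overlap (RRHO)

Two differential tables are ranked by descending log2 fold change (ties broken
lexicographically by feature id for determinism) and restricted to their
common universe of N features. For every pair of rank thresholds (i, j) on a
grid with step `max(1, N // 100)`, the overlap k of the two prefixes is scored
with the hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(N, i, j). The whole
grid is corrected jointly with Benjamini–Yekutieli, which controls the FDR
under the arbitrary positive dependence created by nested prefixes (BH would
be anti-conservative here). −log10 p values are capped at 320 to stay inside
double precision. The shared top signature takes the n_top genes ordered by
mean rank among those present in both prefixes.

## OCR-to-gene linkage

A peak links to a gene when it overlaps the half-open window
`[tss − w/2, tss + w/2)` by at least one base, with w = 40 kb by default and
the TSS taken strand-aware from the annotation. Intervals are indexed with an
interval tree; peaks on chromosomes absent from the annotation stay unlinked
with a warning. Downstream:

- **Status frequency by linkage stratum** — genes stratified into 0/1/2/≥3
  linked gained peaks (or any-gained vs stable-only); proportions per stratum
  sum to 1.
- **Gained-OCR enrichment** — 2×2 χ² without continuity correction; the
  one-sided p is half the two-sided p when the module is enriched and
  `1 − p/2` when depleted. A zero margin raises an error directing to an
  exact Fisher test.
- **Effect-by-count trend** — one-sided permutation test (10 000 label
  permutations by default) using the covariance between stratum index and
  log2FC; p = (1 + hits) / (1 + permutations).
- **mRNA–protein concordance** — features categorised per layer with
  |log2FC| > 0.58 (linear 1.5×) at FDR < 0.05 (mRNA) / < 0.15 (protein),
  strict inequalities; Pearson r² of protein on mRNA log2FC within each mRNA
  category, NaN below 3 pairs.

## Co-expression modules

Expression is z-scored per feature within each condition × time group before
network construction, so correlations reflect co-variation rather than the
treatment design (without this, the planted treatment shifts dominate every
correlation and all induced modules merge). The unsigned adjacency is
`a_ij = |cor(x_i, x_j)|^β` with β = 10 for mRNA and β = 14 for protein — the
customary soft-threshold powers for unsigned networks at these sample sizes.
Topological overlap is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with connectivity `k_i = Σ_{u≠i} a_iu` and TOM_ii = 1, computed with matrix
products (`A·A − 2A` gives the shared-neighbor sum because the diagonal of A
is 1). Modules are average-linkage clusters of 1 − TOM cut at height 0.99;
clusters below 20 members stay unassigned (label 0). The module eigengene is
the first right singular vector of the standardized member submatrix, scaled
to unit variance and oriented to correlate non-negatively with the mean
member profile. Modules are merged iteratively — always the closest pair by
eigengene correlation distance, eigengenes recomputed after each merge —
while that distance is below 0.25, so the fixed point has no surviving pair
under the threshold.

Module quality is a resampling Z: for each resample, samples are bootstrapped,
the network rebuilt, and a size-matched random feature set plays the module's
role; the observed density (mean intra-module adjacency) and separability
(density minus mean member-to-nonmember adjacency) are standardized against
this null and Z_summary is their median. 100 resamples by default (1000 for a
publication-scale run); > 2 reads as moderate, > 10 as high quality.

Note the eigengene orientation rule makes the eigengene itself track its
members: negating the input matrix negates the eigengene. A sign-flip
*invariant* eigengene is mathematically incompatible with any deterministic
orientation toward the members, and tracking orientation is what the merge
distance needs.

## Cross-layer module overlap

Module memberships are first restricted to selected features — DEG: linear
|fold change| > 1.5 (strict) at FDR < 0.05; DAP: p < 0.05 (strict) — then
every mRNA × protein module pair is scored with the hypergeometric upper tail
over a universe defaulting to the union of all (restricted) members, and
BH-corrected. A pair is significant when FDR < 0.05 **and** it shares at
least 10 members; the count gate keeps tiny-but-clean overlaps from reading
as biology.

ΔPSI stratification groups splicing events into removal (ΔPSI ≤ −0.2,
FDR < 0.05), retention (ΔPSI ≥ 0.2, FDR < 0.05) and unchanged, and compares
protein log2FC across groups with a permutation ANOVA F test; an empty group
skips the test with a warning.

## Network connectors and communities

For a candidate node v with degree d_v (out-degree in a directed regulatory
network, so only regulator→target edges count) and k neighbors inside a
module of effective size m′ (members present in the network, excluding v),
the enrichment p is P(X ≥ k), X ~ Hypergeom(N − 1, m′, d_v), BH-corrected
across candidates. Admission requires FDR < 0.01 **and** k ≥ 5 (protein
networks) or k ≥ 4 (regulatory networks). The FDR default is the stricter of
the two thresholds in circulation for this analysis (0.01 in the methods
description vs 0.05 in a figure legend); 0.01 was chosen and both gates are
parameters.

Overlapping communities follow the EAGLE recipe: maximal cliques of ≥ 6 nodes
seed the candidate communities; the pair with the largest
`|C1 ∩ C2| / min(|C1|, |C2|)` is merged repeatedly; the dendrogram is cut at
the level with maximal extended modularity EQ (node pairs down-weighted by
the number of communities containing each node); nodes only in smaller
cliques attach to the community sharing most edges with them (ties attach to
all); communities below 2 nodes are dropped. Clique enumeration is guarded at
2000 nodes — the method targets desk-scale module neighborhoods.

## Synthetic generators: scope and limits

All matrices are Gaussian on the log2 scale. The downstream statistics act on
log fold changes and correlations, so a count layer would add nuisance
(normalization, dispersion) without exercising more of the analysis — this is
the main deliberate simplification.

- **Expression** — module members load on a shared latent factor,
  `x = √ρ·z_m + √(1−ρ)·ε`, giving expected pairwise member correlation ρ
  (0.8 by default). Treated samples receive per-module, per-time mean shifts
  of magnitude `effect_sd · (0.5 + |N(0,1)|)` — bounded away from zero, and
  `effect_sd = 0` still yields an exact null. Signs are structured like the
  emulated response: two of every three modules up, one down, direction
  persistent across time points. The protein layer carries 0.8× the mRNA
  effect with extra decoupling noise on downregulated modules (mirroring the
  weaker down-concordance between layers) and its own latent factors.
  Generator-internal differential tables are plain Welch t + BH — scaffolding,
  not an analysis claim.
- **Peaks** — each peak targets a uniformly chosen gene and lies entirely
  inside its window; it is "gained" with probability 0.9 when the target is
  upregulated and 0.1 otherwise. No dose–response is planted: the frequency
  of upregulation responds to gained-peak count, effect magnitude does not,
  so the permutation trend test is expected null on synthetic data.
- **Ranked pairs** — exact construction: the two prefixes share exactly
  `n_shared_top` ids and are disjoint otherwise (requires
  `2·top_size − n_shared_top ≤ n`); everything else is shuffled.
- **Background network** — Erdős–Rényi at p_edge with `connectors` extra
  nodes each wired to `k_connector` distinct module members plus background
  edges at the background rate; an optional planted clique gives the
  community stage recoverable structure.

Not emulated: read-count noise, batch effects, missing proteomics values,
peak-width/signal distributions, genomic correlation structure along
chromosomes, and realistic network topology (scale-free degree
distributions).

## Numerical and design choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf(k − 1, …)`; FDR
  corrections from `statsmodels` (`fdr_bh`, `fdr_by`). `hypergeom_tail`
  validates `0 ≤ k ≤ min(K, n) ≤ N` and returns exactly 1.0 at k = 0.
- The one-sided χ² uses no continuity correction; the worked value for
  table [[30, 70], [10, 190]] is χ² = 36.058 (the Yates-corrected 33.93 is
  deliberately not used).
- −log10 p values are capped at 320 (beyond double-precision underflow).
- Clustering uses `scipy.cluster.hierarchy` on the condensed 1 − TOM;
  eigengenes use SVD rather than covariance eigendecomposition for
  stability.
- Manifest JSON is written with sorted keys and fixed indentation so equal
  config + seed gives byte-identical manifests.
- Derived seeds are drawn as integers below 2³¹ from a `numpy` Generator
  seeded by the run seed; no global random state is touched.

## Limitations

- Property-based validation replaces dataset-level reproduction: headline
  numbers from real deposited datasets (peak counts, module counts, specific
  gene lists) are out of scope at desk scale.
- The quality-Z null (bootstrap columns + size-matched random modules) is a
  pragmatic stand-in for full module-preservation permutation schemes; its
  Z values are comparable within a run, not across datasets.
- The community stage is quadratic-ish in seed cliques and guarded at 2000
  nodes; it is meant for module neighborhoods, not whole interactomes.
- Generator-internal Welch t tests assume roughly equal per-feature variance
  structure; they exist to produce plausible differential tables, not to
  benchmark differential-expression methods.
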