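# Methods

`dimorphnet` re-implements, as a tested and reusable pipeline, a
multi-omics integration strategy for identifying disease-associated
coexpression modules and pathways from population-scale data, merging them
into non-redundant supersets, and predicting key driver genes on gene
regulatory networks — stratified by condition (for example sex × tissue).
Because no public cohort at the original scale is bundled, every stage is
exercised against a synthetic cohort with planted, recorded ground truth.
This note describes the models, the defaults and why, and what a green test
does and does not establish.

## The synthetic cohort (stated world)

The generator emulates the data layers of a ~100-strain mouse panel at desk
scale. Defaults: 200 samples, 1500 genes, 20,000 SNPs.

**Expression.** Planted module *m* of size *s_m* follows a latent-factor
model: gene *g* in module *m* has profile `sqrt(rho)·f_m + sqrt(1-rho)·eps`,
with one standard-normal factor `f_m` per sample. Expected pairwise
within-module correlation is exactly `rho` (default 0.64); background genes
are independent standard normals. Module sizes default to 30–150 genes,
within the 20–500 range used for negative controls. The trait is
`sum_m beta·f_m + noise` over the chosen trait modules (default the first
two, standardized effect `beta = 0.5` each), then standardized.

**Genetics.** Genes sit evenly spaced (50 kb apart, 10 kb bodies, 1-based
inclusive coordinates) on one synthetic chromosome; only distances matter
downstream. A fraction of genes (`eqtl_rate = 0.3`, on the order of the
cis-gene fraction in tissue eQTL panels) receives 1–3 cis-eSNPs within
±1 Mb of the gene body, with eQTL P drawn log-uniformly below 1e-6. GWAS
P-values are Uniform(0,1) — except eSNPs of the "causal" pathways, which
draw from Beta(a, 1) with `a = gwas_enrich_strength = 0.2` (median P
≈ 0.03). The Beta(a,1) family is a stand-in for an unknown enrichment
shape; no test depends on its specific form, only on stochastic dominance.
Genes of enriched pathways are always given at least one eSNP so the
planted signal is fully mapped (the stated world of "planted sets of 50
mapped genes"); mapping failures would otherwise conflate generator
sparsity with detection power. LD blocks are positional runs of 10
consecutive SNPs — any grouping with "one eSNP per block" semantics
suffices for what the pruning step must guarantee.

**Network.** An Erdős–Rényi background (mean degree 3, the sparsity regime
of curated regulatory networks) over non-hub nodes, plus `n_drivers = 3`
planted hubs, each wired to exactly `hub_degree = 40` neighbors of which
70% are disease genes. Hubs are excluded from the background layer so their
degree is exact by construction.

What this world does **not** contain: genotypes, kinship or population
structure, heteroscedastic expression noise, signed regulation, scale-free
degree distributions, or hub structure inside coexpression modules. In
particular, because module genes are exchangeable under the latent-factor
model, intramodular connectivity ranking carries no signal — see
*Preservation* below.

## Coexpression modules

Unsigned adjacency `|corr|^beta` with `beta = 6` (the conventional unsigned
default; the exponent is exposed). Topological overlap:

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with unit diagonal; `dissTOM = 1 - TOM` is the clustering distance.

*Agglomerative*: average-linkage hierarchical clustering with a **static**
cut (default height 0.99; minimum module size 20). A static cut keeps the
procedure dependency-free and deterministic; dynamic tree cutting is out of
scope. Each gene lands in at most one module; sub-threshold clusters pool
as unassigned. Module ids order by size, then smallest gene id.

*Divisive*: the dissTOM graph is sparsified to the strongest 5% of edges;
shortest-path distances are computed per connected component, and a
deterministic k-medoids (1-medoid then farthest-point seeding, PAM-style
alternation, ties to the lowest gene id) recursively splits each cluster
for k = 2..4. A split is accepted when the pooled mean within-cluster
shortest-path distance improves by more than 5% relative to the parent —
an explicit reading of "no more compact child cluster found", which has no
canonical formula. Accepted levels emit modules tagged with their scale; a
gene may appear in one module per scale.

**Eigengene**: first principal component of the gene-standardized
submatrix, unit-norm loading, sign fixed so the mean gene–eigengene
correlation is non-negative. **Trait filter**: Pearson correlation of
eigengene and trait, two-sided P from the t-distribution (n−2 df), kept at
P < 1e-3. **FPR calibration**: 1000 random gene sets of 20–500 genes; FPR
= FP/(FP+TN) at the chosen threshold, displayed at one significant figure.
The calibrated FPR measures how strongly the trait is embedded in the
expression correlation structure: with independent data it sits at the
nominal 1e-3; at desk scale, where the planted trait modules are ~13% of
all genes, it is far higher — a deliberately exposed property, not a bug.

## Preservation

For each reference module shared (≥10 genes) with the test dataset:
density statistic = mean within-module adjacency in the test data;
connectivity statistic = correlation of intramodular connectivity vectors
between datasets. Each becomes a Z against 200 size-matched random gene
sets; `Z-summary = (Z_density + Z_connectivity)/2`, preserved when > 2
(threshold kept verbatim; the reference implementation aggregates more
statistics — this is a deliberate simplification, which is why preservation
tests are property-based rather than value-matched). In the latent-factor
world the connectivity Z hovers near zero by construction (exchangeable
module genes), so preservation is carried by density; real data with
genuine hub structure engages both components. When reference and test data
are identical the connectivity null degenerates (sd = 0); the Z is then
defined as 0, which is the conservative choice.

## Marker set enrichment (MSEA)

Genes → eSNPs: eQTL P < 1e-6 and SNP within ±1 Mb of the gene body.
LD pruning keeps one eSNP per block — the one with the best eQTL P, ties by
smallest SNP id (the selection rule is unspecified in the field's
description; best-eQTL is the information-preserving choice and
deterministic). The enrichment statistic over the pruned markers:

    chi = sum_{i=1..10} (O_i - E_i) / (sqrt(E_i) + 1)

with thresholds at the GWAS background order statistics for top fractions
f_i evenly spaced in [0.50, 0.999] (the count and range are standard; the
spacing is a choice, exposed as a parameter). `E_i` uses the *empirical*
background fraction at each threshold rather than the nominal f_i, so ties
in P-values cannot bias O−E; the statistic is therefore exactly rank-based
and invariant under any strictly monotone transform of all P-values.

Significance: 1000 random gene sets matched on gene count (not marker
count — marker counts then vary naturally, as in the real pipeline), mapped
and pruned identically; the primary P is the one-sided Gaussian tail at the
null mean/sd, with the empirical P (floored at 1/(n_null+1)) reported
alongside. BH FDR < 0.05 across tested sets; zero-marker sets are reported
as unmapped and excluded from the correction. Numerical agreement with the
original implementation's scores is not claimed — calibration (type-I
error ≈ 5%) and planted-signal recovery are the acceptance surface.

## Supersets

Significant sets merge when overlap ratio > 0.33 **and** one-sided Fisher
exact P < 0.05/C (Bonferroni over all C set pairs; whether the original
corrected over all or only overlapping pairs is unstated — all pairs is the
stricter reading, and C is logged). The overlap-ratio denominator is the
smaller set (also unspecified originally; the permissive reading that lets
a small module merge into a large pathway). Merging is transitive via
connected components, which guarantees the output partition is pairwise
non-qualifying and idempotent. Sets sharing an annotation term but failing
the quantitative criteria are never merged by name; a report lists them.

## Key driver analysis (KDA)

Input networks are unioned with direction and weight discarded (conflicting
directions across source networks make the undirected union the robust
choice); self-loops drop. Every node with ≥5 depth-1 neighbors is scored
per superset with the same modified chi-square form, which for binary
membership collapses to a single term:

    chi = (O - E) / (sqrt(E) + 1),   E = n_neighborhood · K / N

The null is the chi of random nodes from the same network (1000 draws per
superset). The one-sided Gaussian tail P is **floored by the exact
hypergeometric tail** of the overlap given the neighborhood size: with
neighborhoods of 5–12 nodes the null chi is heavily discrete, and a
Gaussian fitted to it otherwise awards, say, P ≈ 3e-5 to an overlap of 2 in
a 5-node neighborhood whose exact conditional tail is 0.015. The floor
restores null calibration (zero false drivers in ≥90% of null graphs)
without costing power on genuine hubs, at the price of deliberate
conservatism at the nominal 5% level for tiny neighborhoods. BH FDR within
each superset; FDR < 0.05 defines key drivers, and the best five per
superset ("top" drivers) seed the reported subnetworks (depth-1 induced
subgraphs, with nodes tagged by superset membership and known-gene status).

## Cross-condition comparison

A superset is "shared" between conditions when some superset in the other
condition passes the *same* overlap-ratio + Bonferroni-Fisher criterion
used for merging — the only quantitative overlap rule defined anywhere in
the procedure — otherwise condition-specific. Near-threshold supersets
(FDR < 0.10) are flagged for transparency when FDR values are supplied.

## Determinism and numerics

Every stochastic step is seeded; per-operation substreams derive from the
master seed via `SeedSequence([seed, tag])`, so an identical configuration
yields byte-identical output files. K-medoid and LD-prune ties break by
lowest id. Zero-variance genes drop at load with a warning. Permutation Z
with null sd = 0 maps to 0 when the observation matches the null mean and
±inf otherwise. Coordinates are 1-based inclusive in every table.

## Known limitations

- Static tree cut, no dynamic cutting or eigengene-based module merging.
- The divisive scheme approximates a multiscale embedding approach only in
  spirit (shortest-path k-medoids on a sparsified graph); no planar
  filtering.
- Preservation aggregates one density and one connectivity statistic, not
  the full reference battery.
- MSEA null sets are size-matched by gene count; sets sharing markers are
  tested independently (no marker ownership).
- The KDA weight hook is unused: the implemented statistic is the
  unweighted special case, matching unweighted union networks.
- Samples are treated as exchangeable in the trait correlation (strain
  structure is not modeled).
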