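# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a user re-implementing or auditing
the package would need.

## Preprocessing

Counts are rarefied to a common depth (default **85,000 reads/sample**) by
multivariate-hypergeometric subsampling — drawing without replacement from
each sample's reads — so rarefied columns are exact draws from the
sampling-without-replacement null rather than multinomial approximations.
Samples below the depth are dropped with a warning (an error would make
partially sequenced datasets unusable).

Taxa are then filtered on the rarefied table: a taxon is kept iff it is
non-zero in at least `ceil(0.20 × n_samples)` samples **and** its relative
abundance summed across samples is at least **0.005**. Both rules are
re-applied within every sample group (all / season / region) before that
group's network is inferred, because prevalence and abundance are
group-relative quantities. The summed-abundance rule is a literal sum of
per-sample relative abundances (it can exceed 1), not a mean. A tie at
exactly the prevalence threshold is kept.

To compare networks of different groups on an equal footing, seasonal
groups are subsampled uniformly (without replacement, one seeded generator
for both axes) to **18 samples × 340 taxa** and regional groups to
**31 × 384** before inference; the all-samples network uses everything.

## Correlation inference

Associations are Spearman rank correlations: midranks, then the Pearson
formula on ranks; two-sided p-values use the t-approximation on n − 2
degrees of freedom. Zero-variance taxa (possible after rarefying small
subsets) get ρ = 0, p = 1 for all their pairs and are flagged rather than
raising. The matrix is computed directly from ranks (`rankdata` +
`corrcoef`) because library all-pairs helpers degenerate when any row is
constant; the test suite pins the matrix to both a hand-written
rank-Pearson oracle and pairwise `scipy.stats.spearmanr`.

Multiple testing is controlled with Benjamini–Hochberg step-up q-values
over the full strict upper triangle (T(T−1)/2 tests). BH was chosen over
local-fdr estimation because it is closed-form, deterministic, and the
pipeline only consumes a Q < 0.05 gate.

## Network enhancement

The enhancement step denoises the |ρ| matrix by diffusion:

1. **Localize**: keep each node's K strongest weights
   (K = min(20, ceil(N/10)) by default), symmetrise by averaging.
2. **Normalise**: scale the localized matrix to a symmetric
   doubly-stochastic operator T (symmetric Sinkhorn balancing; isolated
   rows stay zero).
3. **Diffuse**: the fixed point of `W ← α·T·W·Tᵀ + (1−α)·T` with α = 0.9,
   computed in closed form through the eigendecomposition of T — for
   T = VΛVᵀ the fixed point is V·diag((1−α)λ/(1−αλ^order))·Vᵀ, order 2
   matching the recurrence. Transitively supported edges (triangles,
   dense neighbourhoods) are amplified; unsupported edges decay.
4. **Restore scale**: the stochastic fixed point carries unit mass per
   node, so the self-diffusion share is divided out and each row is
   multiplied by the node's localized strength.
5. **Anchor**: by default each node's strongest enhanced association is
   mapped onto its strongest observed |ρ| (`rescale="node_max"`), so the
   enhanced value of an edge measures its consistency within each
   endpoint's neighbourhood and a single absolute cutoff can be applied
   before and after enhancement. The alternative global anchoring
   (`rescale="max"`, matching only the global maxima) is provided but not
   the default: diffusion mass per edge scales inversely with community
   size, so under a global anchor an absolute cutoff silently deletes
   every edge of any community larger than K — an artefact of the anchor,
   not of the data. Either way no enhanced edge exceeds the input's
   off-diagonal maximum.

An edge enters the co-occurrence network iff **p < 0.01, q < 0.05,
|ρ| > 0.6 (strict) and the enhanced weight > 0.6**. Edge weight is the
signed ρ; the sign is restored after enhancement (diffusion requires
non-negative input). Isolated taxa are dropped from the network but
nothing else; taxa isolated later by attacks remain (see below).

Taxa–environment associations use the looser published gates **p < 0.05,
q < 0.05, |r| ≥ 0.6 (inclusive)**, BH-adjusted over the taxon × variable
family separately from the taxon–taxon family, with pairwise-complete
handling of missing environmental values.

## Topology

Edges are treated as **unweighted** for all path-based quantities
(diameter, average path length, betweenness): correlation magnitude is a
similarity, not a distance, and integer diameters indicate hop counts.
Average path length is the mean over connected pairs only (otherwise
undefined for multi-component networks); the diameter is that of the
largest component. Local clustering of degree-<2 nodes counts as 0 in the
average (conventions differ; this one is stated for reproducibility).
"Components" are connected components; "clusters" are Louvain communities
(resolution 1, unweighted, seeded, one run per seed — no consensus step,
for determinism). Fragmentation is f = log(CL)/log(N), base-invariant.
Betweenness is exact Brandes accumulation with each unordered pair counted
once; normalized degree is degree divided by the total edge count (so it
sums to 2 over the network).

Small-world reference: G(n, m) Erdős–Rényi graphs with exactly the
observed node and edge counts; a network is called small-world when its
clustering exceeds the null mean by more than 2 null standard deviations
while its path length stays within 2.

## Stability

Attack experiments remove the top-k (default 10) nodes per round under a
criterion (mean relative abundance, degree, betweenness, or uniform
random) and record N, CL, f, E and modularity after each round. By default
the ranking is **recomputed on the current graph every round** (adaptive);
a non-adaptive flag consumes the original ranking instead, since the two
readings of "iteratively removing" differ. Nodes isolated by a removal
stay in the graph and count toward CL — they were community members, and
their disconnection is precisely the fragmentation being measured.
Ranking ties break lexicographically by taxon id for determinism.

Degree–betweenness coupling is the Spearman correlation across nodes of
(normalized degree, betweenness); high coupling means bridges are also
hubs, i.e. the network has stand-ins when a gatekeeper is lost. Two
networks' couplings are compared by a node bootstrap (resample the paired
centralities within each network B = 1000 times, centre the distribution
of ρ*₁ − ρ*₂ on its mean, two-sided p = fraction at least as extreme as
the observed difference). A bootstrap was chosen as the assumption-light
Monte-Carlo comparison; B and the seed are exposed.

## Synthetic data

The generator emulates the post-QC statistical structure of a rarefied
estuarine 16S dataset: **84 samples** (7 stations × 4 seasons × 3 years)
with temperature following the seasonal cycle (winter < spring < autumn <
summer means), salinity rising monotonically downstream ~0→30 PSU, TSS
and nutrient load falling downstream, and Chl a / particulate carbon
covarying with temperature and the freshwater end.

The community model is a latent Gaussian factor model on log abundance.
Each guild g has a standardised factor Z_g mixing a shared seasonal
forcing component (pairwise overlap corr(Z_a, Z_b) = w, default 0.4;
guild-specific parts are orthogonalised so the overlap is exact) with a
Gaussian niche response along temperature or salinity and a biotic
component. A member taxon is
`x_t = μ_t + √ρ·Z_g + √(1−ρ)·ε_t + sd·ν_t` with target within-guild
correlation ρ and extra dispersion sd. Antagonist guild pairs share a
factor with opposite signs (planted negative associations). Gatekeepers
load on the standardised sum of two bridged guild factors at low mean
abundance; bridged pairs are disjoint, so each bridge is essential and
its removal fragments the network. Counts are a single multinomial draw
of `depth` reads over softmax(x) per sample — compositional with fixed
totals, like a rarefied table (not independent Poisson).

Defaults: 14 guilds × 10 taxa + 12 gatekeepers + 248 unstructured
background taxa = 400 taxa; ρ = 0.95; w = 0.4; gatekeeper loading 1.0 and
mean log abundance −1.5 (≈15 reads/sample, bottom decile); noise sd 0.2;
depth 85,000. Three calibration facts shaped these numbers, all
consequences of the compositional count model rather than free choices:

- softmax + multinomial counting attenuate rank correlations by roughly
  5–10%, so a latent ρ = 0.95 realises near 0.9 — the strength range of
  retained edges in real estuarine networks;
- a taxon bridging two *independent* guilds cannot exceed correlation
  √(ρ/2) ≈ 0.69 with either, which counting noise pushes under the 0.6
  edge threshold; the shared forcing overlap raises the ceiling to
  √((1+w)/2)·√ρ ≈ 0.81 while cross-guild member pairs stay sub-threshold
  (w·ρ ≈ 0.38);
- with α = 0.9 the diffusion barely damps the bottleneck (Fiedler) mode,
  so a single weakly-attached bridge node is assigned wholly to one side
  and enhancement deletes its other side's edges; gatekeepers need the
  headroom above 0.6 on both sides to survive, as they evidently do in
  real, far leakier correlation structures.

What the generator does **not** emulate: read-level error and chimeras,
taxonomic assignment uncertainty, absolute-abundance dynamics, autocorrelated
time series within a station, overdispersion beyond the log-normal-ish
latent, and the heavy-tailed abundance distribution of real communities.
Passing recovery tests therefore show that the inference machinery
retrieves the structure this model plants at these signal strengths — not
that it would retrieve weaker or differently structured associations in
real data.

## Problem sizes used in the test suite

The default end-to-end configuration (84 × 400, seven networks, three
attack criteria) runs in a few seconds on one CPU and is exercised at
full scale in the acceptance tests; unit tests use smaller communities
(tens of taxa) and graphs of ≤ 150 nodes. Exhaustive betweenness oracles
run on graphs of ≤ 12 nodes; the rarefaction distribution check uses
20,000 replicate draws of a 2-taxon sample.

## Known limitations

- The enhancement anchoring (step 5) is a methodological choice; results
  near the 0.6 cutoff can differ between anchorings. Both are exposed.
- BH q-values are tail-area FDR, not local fdr; with the additional
  |ρ| > 0.6 gate the practical difference on edge sets is small.
- Louvain is run once per seed; partitions (and Q) can vary slightly
  across seeds on networks with weak community structure.
- The bootstrap coupling comparison treats nodes as exchangeable units;
  it ignores the dependence induced by shared edges.
- Family-level aggregation groups unresolved lineages under their most
  resolved rank; two genuinely different unclassified families under the
  same order are merged.
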