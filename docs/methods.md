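# Methods

`benthocouple` implements a two-habitat (pelagic / benthic) analysis of
eukaryotic eDNA metabarcoding count tables: from amplicon sequence
variants (ASVs) to co-occurrence networks, environment-correlated
subnetworks, keystone ASVs, and a cross-habitat graph alignment that
quantifies how strongly the seafloor community mirrors the overlying
water column ("pelagic-benthic coupling" via sinking organic matter).
This note records the models, the defaults and why they are what they
are, and what the synthetic benchmark does and does not demonstrate.

## Preprocessing (`asv_io`)

ASV tables are samples x ASVs integer count matrices with optional
ranked taxonomy (division ... species) and representative ~380 nt
marker fragments. Preprocessing applies, in order:

1. **Singleton removal** — ASVs with a total count of 1 are noise-prone
   and inflate spurious associations.
2. **Abundance/prevalence filter** — the default keeps an ASV only if
   it has >= 50 reads in each of >= 3 samples (`min_total=50`,
   `min_samples=3`). The phrase "50 reads in at least three samples"
   admits a weaker reading (total >= 50 and detected in >= 3 samples);
   both are implemented (`per_sample=False`), the stricter one is the
   default because the downstream correlation machinery benefits from
   ASVs whose profiles are quantitatively informative in several
   samples, not merely present.
3. **Closure and CLR** — counts are closed to relative abundances and
   transformed with the centred log-ratio, `clr(x) = log x - mean(log
   x)` per sample, which removes the unit-sum constraint that induces
   spurious negative correlation in compositional data. Exact zeros are
   replaced beforehand by half the smallest strictly positive relative
   abundance **of the whole matrix** (not per sample), so the
   imputation is a single constant and CLR values remain comparable
   across samples.

Alpha diversity (Shannon, Gini-Simpson, Chao1 with the
`S_obs + F1(F1-1)/(2(F2+1))` small-sample form) and seeded rarefaction
(subsampling without replacement; its Monte-Carlo mean converges to the
closed-form hypergeometric expectation) are provided for the usual
depth-adequacy checks.

## Co-occurrence network (`network_inference`)

The association network is a conditional-independence graph over CLR
profiles (plus optional environmental meta-variables as extra nodes).
For each variable pair the marginal Pearson correlation and the partial
correlations given every subset (size <= `max_k`, default 3) of a
bounded candidate-neighbour pool are tested with Fisher's z; the pair's
evidence is its **weakest** p-value, and Benjamini-Hochberg at
`fdr=0.05` over all pairs decides which edges survive. An edge
therefore means "directly associated, not explainable by up to three
observed covariates". Edge weight is the marginal correlation; its sign
distinguishes co-occurrence from exclusion.

Numerical choices: the candidate pool per node is its 20 strongest
marginal partners; a per-pair pool is capped at the 10 strongest
(deterministically — no subsampling), keeping the subset scan at most
~176 tests per pair. Pairs whose weakest evidence already exceeds the
FDR level are abandoned early, which cannot change the result (the BH
threshold never exceeds the level). Inference is deterministic and
invariant to column order.

Node importance uses normalised degree centrality (`deg/(n-1)`) and
unnormalised shortest-path betweenness.

## Subnetworks (`subnetworks`)

Modules are delineated in the weighted-correlation-network style:

- signed adjacency `a_ij = ((1 + r_ij)/2)^beta`, soft-thresholding
  power `beta = 6` (the convention for signed networks; anticorrelated
  pairs map near 0, not to high adjacency);
- topological overlap
  `TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`,
  which rewards shared neighbourhoods and is far less noisy than raw
  adjacency;
- average-linkage hierarchical clustering of `1 - TOM` with a **static
  cut**, small clusters (< `min_module_size = 10`) left unassigned
  (label 0), modules renumbered by descending size.

The cut height defaults to automatic selection: the cut is placed in
the widest gap among the upper half of the dendrogram's merge heights.
A fixed numeric height is brittle here — the absolute TOM scale moves
with the background adjacency `0.5^beta` and with sample size, so any
constant (0.95, 0.99, ...) merges everything in some regimes and
shatters everything in others, while the between/within merge-height
gap is scale-free. Passing `cut_height=<float>` restores a plain static
cut. When all merges happen at one height (no structure) everything is
left unassigned.

The module **eigengene** is the first principal component of the
module's standardized member profiles, unit-norm over samples,
sign-oriented so it correlates non-negatively with the module's mean
standardized profile. Eigengene-environment association uses plain
Pearson correlation with exact t-based two-sided p-values,
pairwise-deleting missing trait values, and a hard significance
threshold of `p < 0.005` with no further multiplicity correction — the
threshold is deliberately strict instead.

## Keystones (`keystone`)

A PLS1 regression (NIPALS, via scikit-learn) relates CLR profiles to a
carbon response — particulate-organic-carbon (POC) flux for the water
column, sediment organic-carbon content (Corg) for the seafloor. The
component count is chosen by leave-one-out cross-validation with a
one-standard-error rule, capped at 10. Variable importance in
projection is

    VIP_j = sqrt( p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a )

with `SS_a` the response variance explained by component `a`; the mean
of squared VIPs is exactly 1, making VIP a self-calibrating scale
(VIP > 1 = above-average influence). Keystone ASVs are ranked by the
product of rank-normalised degree centrality and rank-normalised VIP —
a thresholds-free combination that demands *joint* structural and
predictive importance; ties break on ASV id.

## Graph alignment (`graph_alignment`)

Carbon-correlated subnetworks of the two habitats are aligned by an
injective node mapping `f` maximising

    J(f) = alpha * sum_{u in dom f} seqsim(u, f(u)) / min(|V_A|, |V_B|)
         + (1 - alpha) * S3(f)

with `alpha = 0.4` by default: `alpha = 0` is purely topological,
`alpha = 1` purely sequence-based. The sequence term is normalised by
the maximum alignable pair count rather than by `|dom f|`: with a
`|dom f|` denominator the sequence term is maximised by aligning only
the single best pair, which contradicts both desired limits (at
`alpha = 1` the alignment should reproduce each node's best sequence
partner when those are distinct). With the fixed denominator every
credible pair helps the sequence term while the S3 term vetoes pairs
that break topology — which is also what allows the alignment to stay
*partial*, as real cross-habitat alignments are.

- **Sequence similarity**: identity (matches / alignment columns) of
  the optimal unit-cost Needleman-Wunsch global alignment, computed
  with edlib. Identical fragments score 1; one substitution in 100 nt
  scores 0.99.
- **Topological similarity**: graphlet-degree vectors over the 15
  orbits of connected 2-4-node graphlets (counted by ESU enumeration
  of induced subgraphs), compared on a log scale with orbit weights
  that down-weight redundant orbits; mapped to [0, 1].
- **Quality scores**: edge correctness `EC = C / |E_A[dom]|` and the
  symmetric substructure score `S3 = C / (|E_A[dom]| + |E_B[img]| - C)`
  (C = conserved edges); `S3 <= EC` always.
- **Optimiser**: deterministic multi-start search — an unconstrained
  greedy, greedies forced to start from each top node-similarity pair
  with distinct endpoints, and Hungarian (maximum-weight assignment)
  starts on the blended and the sequence similarity matrices — each
  followed by best-improvement hill climbing over add / drop /
  reassign / swap / transfer moves. Every accepted move strictly
  increases J, so termination is guaranteed. On exhaustive-search
  instances (<= 6 nodes) the optimiser reaches >= 98% of the optimum;
  the Hungarian start makes the `alpha = 1` limit exact.

`coupling_summary` reports aligned/possible node counts (possible =
size of the smaller node set by default; a union convention is
available), the fraction of aligned pairs sharing a taxonomic division,
self-aligned ASVs (sequence identity 1 and identical id or lineage —
the signature of direct export), a division-to-division flow table
(alluvial input), and shared-family counts (Venn input).
`hiveplot_layout` emits the node table (axis, abundance rank,
internal/external group, centrality size) for hiveplot rendering;
plotting itself is out of scope.

## Synthetic coupled communities (`synthetic_data`)

The generator plants exactly the structure the pipeline claims to
recover, at the study's scale:

- **Environment**: POC flux as a rectified sinusoid (bloom pulses) —
  baseline 10, amplitude 30 mg C m⁻² d⁻¹, period 12 samples — plus
  Gaussian measurement noise (sd 2); season index and longitude
  columns. Benthic metadata carry sediment Corg (%).
- **Modules**: 4 modules x 30 ASVs per habitat, 60 samples. Module
  eigengenes are AR(1) series (coefficient 0.6); the *carbon module*'s
  pelagic eigengene loads 0.8 on standardized POC. The benthic carbon
  eigengene is the lag-1-smoothed pelagic one (export delay without a
  sinking-speed model), and Corg is built from it (loading 0.35).
- **Members**: each ASV's latent log abundance is
  `base + 0.8 * eigengene + 0.55 * pair_factor + resid * noise`, where
  consecutive module members form disjoint partner pairs sharing a
  latent factor. The pair factor models *direct* ecological
  associations: a pure one-factor module renders all within-module
  pairs conditionally independent given the eigengene, so a
  conditional-independence network over it is — correctly — empty, and
  nothing would exercise the network stage. The weight 0.55 makes a
  partner edge reliably detectable at n = 60 given the 0.8 eigengene
  loading (their squares must sum to <= 1). Exported pairs inherit the
  lag-smoothed pelagic pair factor, so coupled subnetwork topology is
  conserved across habitats.
- **Counts**: multinomial draws of 20,000 reads per sample from the
  softmax of latent log abundances — compositional by construction,
  which is precisely the distortion CLR is meant to undo.
- **Taxonomy and sequences**: two divisions per module; genera of 5
  consecutive ASVs; per-division random root sequences, genus
  references mutated at 25% divergence, within-genus mutation 2%.
  Export-coupled benthic ASVs copy their pelagic partner's lineage and
  differ from its sequence by 1% substitutions (~4 of 380 nt), so
  coupled pairs sit far above the ~50% cross-habitat background
  identity. `coupling_fraction` (default 0.5 of the carbon module)
  controls how many pelagic carbon ASVs are exported.

What passing the synthetic benchmark does **not** show about real
data: the generator has Gaussian latent dynamics, exact compositional
closure, no sequencing-error or PCR-bias model, no phylogenetic
autocorrelation beyond the genus/division hierarchy, equal module
sizes, and a single planted driver. Real module recovery and coupling
estimates will be noisier and depend on filtering choices; the
benchmark establishes correctness of the machinery, not field
performance.

## Degenerate inputs and tie-breaking

Zero-count samples raise on closure; zero-variance ASVs raise in the
adjacency (and are excluded with a warning in network inference);
constant traits yield NaN correlations flagged non-significant;
singleton modules return their standardized profile as eigengene;
empty networks align to an empty mapping with J = 0. All orderings are
fixed (sorted ids, size-then-id module renumbering, rank ties by id),
so every stage is reproducible bit-for-bit; the pipeline fans a single
global seed out to per-stage seeds.

## Problem sizes used in the checks

The test-suite and the acceptance script work at the generator's
default scale (two habitats x 120 ASVs x 60 samples, 20k reads), with
10-seed replication for recovery claims, 100-200 replicates for
calibration-under-the-null claims, and exhaustive enumeration only on
<= 6-node alignment instances and 10-node TOM matrices. These sizes
were chosen so every stochastic claim is replicated while the whole
suite stays a desk-scale computation.
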