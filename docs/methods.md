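# Methods

This note documents the models and procedures implemented in `biofilmnet`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Synthetic data model

Counts are generated from a logistic-normal-multinomial model, the natural
choice when the downstream inference assumes compositional counts driven by
a latent Gaussian dependence structure:

1. A sparse ground-truth graph over `p` features is built with one of four
   topologies (band, cluster, scale-free, hub). Edge values — signed partial
   correlations — are drawn uniformly from ±[0.15, 0.35]: strong enough to be
   recoverable at ~100 samples, weak enough that recovery is not trivial.
   The precision matrix Ω has −v on edge (i,j) and is made positive definite
   by the smallest diagonal shift leaving a 0.05 eigenvalue margin, then
   rescaled to unit diagonal. A strict diagonal-dominance construction was
   rejected: it inflates the diagonal by up to ~70 %, which halves the
   planted partial correlations after rescaling and makes the graph
   essentially unrecoverable at realistic sample sizes.
2. Latent log-abundances per sample are MVN(μ_g, Σ) with Σ = cor(Ω⁻¹).
   Group effects are log-scale mean shifts per (treatment, substrate) combo
   (uniform ±`effect_size`) and per timepoint (uniform ±`effect_size`/2).
   Bounded rather than Gaussian shifts are used so that no single feature can
   drift into dominating the whole composition of a group. With
   `effect_size = 0` all groups are exchangeable — the basis of the
   type-I-error calibration.
3. Planted structure. Core features of a group and host-specific features of
   a host have their non-boost log-mean floored at 0 and raised by 3 log
   units inside their own groups, so they always clear the read-detection
   thresholds there. Presence/absence is imposed by structural zeros applied
   to the composition before the multinomial draw (multinomial sampling alone
   cannot guarantee absence): a core feature is present in exactly
   round(0.95·n) samples of its group, a host-specific feature in all samples
   of its host's seaweed and proxy-biofilm groups and none elsewhere, and
   every other feature in round(π·n) samples with π drawn uniformly from
   [0.3, 0.8] per feature and group. The exact-count (rather than
   per-sample Bernoulli) dropout keeps planted prevalence deterministic, so
   recovery of the planted sets is an exact, not probabilistic, expectation.
   When no planted structure is requested (network benchmarks, null
   calibration) no dropout is applied at all.
4. Sequencing depths are log-normal (default mean 20 000 reads, dispersion
   0.3 — typical MiSeq amplicon libraries); counts are a single multinomial
   draw per sample, so sample totals equal the drawn depths exactly.

The default study design mirrors a two-experiment host/substrate factorial:
three host treatments × {seaweed surface, proxy-biofilm filter} × two
timepoints × six replicates, plus control filters (six) and ambient seawater
(two) per timepoint — 88 samples.

What passing tests on these data do **not** show: real amplicon data have
taxonomy misassignment, chimeras, overdispersion beyond multinomial,
zero-inflation unrelated to prevalence structure, and compositional effects
of highly dominant taxa; a planted core at deterministic prevalence is
cleaner than any real core. The validation demonstrates correctness of the
algorithms under their own model assumptions, not field performance.

## Community statistics

- Shannon diversity uses the natural log (the convention of the vegan
  ecosystem).
- Bray–Curtis is computed as given (scale-dependent); analyses default to
  relative-abundance input, where it is depth-invariant.
- PERMANOVA uses the distance-based sums of squares
  SS_T = (1/N) Σ_{i<j} d²ᵢⱼ, SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d²ᵢⱼ and the
  pseudo-F with (a−1, N−a) degrees of freedom. Permutation p-values follow
  the (1+b)/(1+m) convention (p can never be 0); `method="exact"` enumerates
  all distinct label arrangements (bounded at 2·10⁵) and divides by the
  count. Strata (e.g. panel blocks) restrict permutations within levels;
  off by default.
- Beta-dispersion embeds samples by PCoA, keeping negative-eigenvalue axes
  with the imaginary-part convention (z² = ‖real‖² − ‖imaginary‖², clipped at
  0), measures distances to group centroids (centroids, not spatial medians —
  the simpler canonical form) and applies a one-way F with a permutation
  p-value on those distances.
- Pairwise PERMANOVA subsets the distance matrix per group pair; multiplicity
  correction defaults to Benjamini–Hochberg.

## Network inference

The inference is the neighbourhood-selection (Meinshausen–Bühlmann) route to
a conditional-dependence graph on CLR-transformed abundances:

- WMC filter: features need ≥ 3 total reads and mean relative abundance
  ≥ 0.25 % (a per-sample-minimum variant is selectable).
- CLR with pseudocount 1 on counts (the standard convention for integer
  tables).
- Each standardized feature is regressed on all others with an L1 penalty;
  the penalty path is 30 log-spaced values from λ_max (= max |X'y|/n, the
  smallest empty-model penalty) down to 0.01·λ_max.
- StARS: 20 subsamples without replacement of size min(⌊10√n⌋, ⌊0.8·n⌋) —
  the published recommendation capped for the small per-group n of
  replicated field designs. Per-edge instability is 2θ(1−θ) with θ the
  cross-subsample edge frequency; total instability is monotonized from the
  sparsest end and the smallest penalty with D ≤ 0.05 is selected (the
  sparsest penalty, with a warning, if none qualifies).
- The final coefficient matrix is refit on the full data at the selected
  penalty with a tight optimizer tolerance (1e-10; the subsampled path fits
  use the looser default since they only feed instability estimates, and the
  densest path ends may stop at the iteration cap).
- Symmetrisation: OR rule by default (an edge exists if either directed
  coefficient is nonzero; AND available). Agreeing coefficients are
  averaged; sign conflicts keep the larger-magnitude coefficient and are
  counted in the log.

Networks are inferred per sample group on the merged prokaryote+microalga
table, so edges may link features across domains.

## Network metrics and roles

All topological metrics are computed on the unweighted graph (weights enter
only mean |weight| and the negative-edge fraction): mean degree 2E/N, density
2E/(N(N−1)), normalized unweighted betweenness, global transitivity
(3·triangles / connected triples; average-local clustering available),
natural connectivity ln((1/N) Σ e^{λᵢ}) over adjacency eigenvalues (0 for an
edgeless graph, strictly increasing under edge addition), and Newman–Girvan
modularity maximized by multi-restart Louvain (exactness verified against
exhaustive partition search on ≤ 8-node graphs in the tests; an edgeless
graph is a single module with Q = 0 by convention).

Node roles use the canonical Zi–Pi scheme: Zi standardises the within-module
degree against the node's module (population SD; Zi = 0 when the SD is 0),
Pi = 1 − Σₘ (k_{i,m}/kᵢ)² (0 for isolated nodes); thresholds 2.5 and 0.62
classify network hubs (both high), module hubs (Zi only), connectors (Pi
only) and peripherals. Both thresholds are exposed.

## Network comparison

Profiles are the fixed-order vector (n_nodes, n_edges, edge_density,
mean_degree, mean_betweenness, transitivity, modularity_Q,
natural_connectivity, prop_negative_edges, mean_abs_weight). Metrics are
z-scored across networks before Euclidean distance and PCA, because raw
metrics have incomparable scales and unstandardized distances would be
dominated by node/edge counts; raw mode is retained for sensitivity
analysis, and zero-variance metrics are dropped with a warning. The PCA
keeps all components up to the matrix rank, so its score distances reproduce
the profile distances exactly. Shared edges between two networks require the
same unordered node pair *and* the same sign — an association that flips
sign across networks is not the same association.

## Pipeline

`run_pipeline` executes simulate → filter → core → stats → network → metrics
→ netcompare from a TOML config. Per-stage seeds are derived from the master
seed by hashing the stage name (so adding a stage never perturbs earlier
stages' randomness), all stage outputs are deterministic TSV, and the run
manifest records version, config hash, per-stage seeds and runtimes. The
bundled `configs/pipeline_small.toml` runs the full factorial design at 40
features with 20 subsamples and a 20-point penalty path per group network —
sizes chosen so that the complete run takes seconds while still exercising
every stage end to end. The validation suite uses 20 replicates at 50
features / 100 samples for network recovery and 200 replicate datasets for
permutation-test calibration for the same reason.

## Known limitations

- Only the neighbourhood-selection flavour of the inference is implemented
  (no inverse-covariance/glasso variant, no edge p-values).
- Modularity optimisation is heuristic beyond small graphs; multi-restart
  mitigates but does not remove local optima.
- The copy-number table is taken as given; features missing from it are
  normalised with copy number 1 and logged.
- Beta-dispersion permutes group labels of the centroid distances (the
  simple form), not residuals.
- The exact-enumeration mode refuses designs with more than 2·10⁵ distinct
  label arrangements.
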