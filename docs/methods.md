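# Methods

## MAG catalog construction

Input bins carry CheckM-style completeness and contamination percentages.
The quality gate keeps bins with completeness strictly above 80% and
contamination strictly below 10%; both comparisons are deliberately strict
so a bin at exactly 80/10 is excluded. Composite quality is
`completeness − 5 × contamination`, the de-facto weighting used by
dereplication tools; it decides every "keep the better genome" choice in
the pipeline.

Dereplication is greedy centroid clustering on the pairwise ANI matrix:
bins are ordered by quality (ties broken by id), the best unassigned bin
becomes a representative, and every unassigned bin with ANI ≥ 98% to it is
absorbed. This construction makes two invariants provable rather than
empirical: every member has ANI ≥ 98% to its representative, and distinct
representatives share ANI < 98%. We chose greedy centroid over
average-linkage because linkage clustering cannot guarantee the
member-representative bound that the downstream probabilistic model
relies on. For ≤ 8 genomes the greedy result provably coincides with an
exhaustive search over centroid orderings under the same tie rules (tested
against that oracle).

Quality-passing bins that are not representatives are then assigned to the
representative with which they share the highest ANI (ties by
representative id). Within each cluster, any pair of non-representative
members from the same host **and** same site/colony with ANI strictly
above 99.5% is treated as a pseudoreplicate — two assemblies of the same
biological strain — and the lower-quality member is dropped. The rule is
applied iteratively until stable; representatives are never dropped, so a
cluster can never empty. Whether such filtering should be single-pass or
iterated is genuinely open; we iterate because a single pass leaves
order-dependent results.

Contig-level refinement (`refine_by_genus`) drops contigs assigned to a
genus other than the target; contigs with no assignment are retained,
since only positive foreign assignments are evidence of contamination.
Re-estimating contamination after refinement is out of scope — the caller
supplies updated values.

## Community profiling

Relative abundances are percentages per sample, summing to 100 together
with an explicit unmapped fraction. All community distances are computed
on mapped-only, renormalized compositions: the unmapped fraction is a
property of the reference set, not a community member, and including it
would let mapping efficiency masquerade as community structure. Shannon
diversity uses natural logarithms (the ecology-package convention);
richness counts features strictly above a detection threshold
(default 0).

PCoA is classical scaling: eigendecomposition of the Gower-centered
matrix −½ J D² J. Negative eigenvalues (non-Euclidean distances) are
reported in full but their axes are not included in coordinates; no
Lingoes/Cailliez correction is applied, matching the defaults of the
standard ordination functions.

PERMANOVA partitions the trace of the Gower-centered inner-product matrix
through projection (hat) matrices built from dummy-coded factors
(McArdle–Anderson). Two-factor designs use sequential sums of squares in
column order, matching `adonis2(..., by = "terms")`, against which the
implementation is pinned to nine digits on a frozen 14-sample fixture.
Permutation p-values use free permutation of samples (rows and columns of
the distance matrix jointly) with the unbiased estimator
p = (1 + #{F\* ≥ F}) / (1 + n_perm), which includes the observed statistic
and so can never return 0. An exhaustive mode enumerates all n!
orderings for small n and returns the exact proportion; the test suite
uses it to verify the sampled mode. Restricted permutation schemes for
nested designs are not implemented; the two-factor model permutes freely.

Numerical care: when a permutation leaves a numerically zero residual
(≤ 1e-12 of total SS), F is set to +∞ and only exactly degenerate
permutations can tie it — otherwise perfect-separation toys return biased
p-values. F comparisons otherwise use a 1e-9 relative tolerance so that
permutation-equivalent relabelings count as ties.

Beta dispersion embeds samples by PCoA keeping negative-eigenvalue axes as
an imaginary component; each sample's dispersion is
sqrt(max(0, |r − m_r|² − |i − m_i|²)) where m_r, m_i are per-group spatial
medians fitted separately on the real and imaginary axes by Weiszfeld
iterative reweighting to tolerance 1e-8. This mirrors
`betadisper(type = "median")`, agreeing with it to ~1e-6 (the reference
optimizer converges to a looser tolerance). Homogeneity is a one-way
ANOVA F on the dispersions with significance from permuting dispersions
across groups; group centers are not refitted per permutation, again
following the reference implementation. Singleton groups get dispersion 0
with a warning.

Pairwise PERMANOVAs run the single-factor test on each pair's sub-matrix
and Bonferroni-correct by the number of pairs, capped at 1.

## Probabilistic metabolic potential

A module is *encoded* by a MAG when its stepwise completeness is ≥ 0.75
(inclusive). Cluster-level relative presence p(c, m) is the fraction of
member MAGs encoding the module, so clusters of size n yield values on
the grid {0, 1/n, …, 1}. A cluster is *present* in a sample when its
representative's relative abundance is strictly above 1%.

Because a sample containing a cluster must contain at least one member
genome — but which member is unobserved — the minimum probability that
module m is present in sample s is

q(s, m) = 1 − ∏ over present clusters c of (1 − p(c, m)),

the at-least-one-carrier probability under independent one-MAG-per-cluster
sampling. When no present cluster can carry the module, q = 0 (the model
cannot place the module in the sample at all). The quantity is a lower
bound by construction: abundance weighting or multi-MAG occupancy could
only raise the probability. q is monotone in both arguments, bounded by
max p ≤ q ≤ min(1, Σp), and verified against exhaustive enumeration of
per-cluster carrier outcomes for ≤ 4 clusters.

Modules are called present at q ≥ 0.75 (inclusive), and per-host
prevalence is the percentage of the host's samples with a positive call.
Classification is a trichotomy: modules with enrichment q-value < 0.05
are *differentially enriched*; the remainder are *consistently present*
when mean per-host prevalence is ≥ 75% and *consistently low* otherwise.
The 75% split is this package's explicit choice — the trichotomy itself
does not pin a numeric boundary — and is a configurable parameter. The
universal-module summary counts consistently present modules at 100%
prevalence in every host and reports an integer percentage rounded half
away from zero.

## Enrichment statistic

Per module, per-group presence proportions p_g (from n_g units each) are
compared with the Rao score statistic
Σ_g n_g (p_g − p̄)² / (p̄(1 − p̄)) on (groups − 1) degrees of freedom,
where p̄ pools all units. For two groups this equals Pearson's χ² of the
2×2 table exactly (tested over every table with group sizes ≤ 6).
Degenerate modules (p̄ ∈ {0, 1}) score 0 with p = 1 and are reported
rather than dropped, keeping module universes aligned across outputs.
The χ² reference is asymptotic; with very small groups its type-I error
drifts, which is why the calibration tests use 12 units per group.
Significance conventions differ by analysis: the cluster-level analysis
uses unadjusted p-values and the host-level analysis uses BH q-values —
each the more conservative choice in its context. BH is the standard
step-up, cross-checked against statsmodels.

## Synthetic data generator

The generator emulates the structure the analysis assumes, at the scale
of a six-host bumble bee survey: 6 hosts × 4–12 samples, 10 genus-level
phylotypes split into ~30 clusters (2–4 each), 1–5 MAGs per cluster
(~80–110 MAGs), 100 modules. All draws flow from one integer seed through
a single generator stream; identical configurations give byte-identical
tables.

- **ANI**: block structure — within-cluster draws uniform on (98.2, 99.4),
  between-cluster on (80, 97.5) — so the true clustering is exactly
  recoverable and the recovery test is sharp. The default within-cluster
  ceiling sits below the 99.5% pseudoreplication bound so that membership
  recovery is exact under defaults; the pseudoreplication filter is
  exercised separately with configurations above the bound.
- **Prevalence**: the first cluster of each host is an exclusive *marker*
  (prevalence 1 in its own host, 0 elsewhere), emulating host-specific
  strains and guaranteeing every sample is non-empty; other clusters are
  carried by each host with probability 0.55, at prevalence uniform on
  (0.5, 0.95).
- **Abundance**: present clusters share (100 − unmapped)% of the sample by
  a symmetric Dirichlet (concentration 1) on top of a 2% floor per
  present cluster, so the >1% presence rule recovers the true presence
  set exactly; the floor shrinks automatically when many clusters
  co-occur. The unmapped fraction is uniform on (5, 45)%, matching the
  wide range such surveys report.
- **Quality**: completeness 100 − Exp(3) clipped to (80.5, 100),
  contamination Exp(0.8) clipped below 9.5 for passing bins; 15% of
  non-anchor bins fail the gate (low completeness or high contamination,
  coin flip). The first bin of each cluster always passes so every
  cluster keeps a representative.
- **Modules**: a global core (fraction 0.4 of the catalog) present in all
  clusters; a redundant pool (fraction `redundancy` of the rest) shared
  by random sets of ≥ 2 phylotypes; the remainder accessory to single
  clusters. A MAG inherits its cluster's set minus dropout at rate
  (100 − completeness)/100, plus sub-threshold completeness noise
  (rate 0.05, values < 0.75) that exercises the presence threshold.
- **Planted enrichment** rewires chosen modules onto the host-marker
  clusters of chosen hosts. Full contrasts (1, 0) are exact; fractional
  targets redraw the marker's per-sample presence Bernoulli(p) and
  rebalance the abundance row, because a purely cluster-level module
  model has no other channel to an expected prevalence strictly between
  0 and 1. Sample-level presence truth is recomputed from the final
  abundances.

What the generator does **not** emulate: read-level noise and mapping
error, compositional correlations between clusters, phylogenetic signal
in ANI (between-cluster ANI ignores phylotype relatedness), covarying
module content between related clusters, and real KEGG module structure.
Passing tests therefore demonstrate correctness of the inference
machinery under the model's assumptions, not robustness to real-data
violations of them.

## Problem sizes in routine runs

The bundled statistics and tests run at deliberately modest sizes chosen
as sufficient for their purpose: null calibration uses 500 replicates
(Monte-Carlo s.e. ≈ 0.01 at α = 0.05) with 199 permutations per PERMANOVA
and 60-module catalogs with 12 units per group; exhaustive-permutation
checks use n ≤ 6; the oracle sweeps cover all 2×2 tables with group sizes
≤ 6 and all ≤ 4-cluster probability configurations on the quarter grid.

## Known limitations

- The greedy centroid dereplication is a deliberate, provable replacement
  for tool-internal clustering heuristics; it will differ from
  linkage-based tools on chained ANI topologies (A–B and B–C close,
  A–C distant).
- The χ² enrichment reference is unreliable below ~5 expected units per
  cell; no exact (Fisher-type) fallback is provided.
- Free permutation is used for the two-factor PERMANOVA; restricted
  (within-block) schemes are not available.
- The minimum-probability model assumes independent single-MAG occupancy
  per cluster and ignores abundance; it is a lower bound, not an
  estimate.
- q(s, m) is computed per sample from that sample's present clusters;
  pooling evidence across samples of a host is intentionally not done.
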