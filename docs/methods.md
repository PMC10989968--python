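# Methods

## Scope and model

micronar quantifies how the complexity and stability of microbial
co-occurrence networks scale with habitat area across an archipelago. The
analysis object is a single *meta-network* inferred once across all samples,
from which one subnetwork per island is extracted; every network property and
stability metric is then a per-island observation regressed on log10 island
area (m²). Working at the meta-network level keeps edge identities comparable
across islands; the alternative — fitting one network per island from that
island's ~10 samples — is statistically hopeless at typical survey depth and
is exposed only as a building-block (the inference functions accept any
sample subset).

Assumptions worth stating plainly:

- Edges are rank correlations of relative abundances across heterogeneous
  samples. They mix biotic association, shared habitat response and
  compositional coupling; nothing here identifies mechanism.
- Correlations are computed on log10(x+1) counts. Spearman is invariant to
  any strictly increasing transform, so the pseudocount is cosmetic; it is
  fixed for reproducibility and because the transformed matrix is also what
  downstream consumers receive.
- Pre-processing order is rarefy → prevalence filter; both the order and all
  parameters are recorded in the output manifest.

## Network inference

All-pairs Spearman ρ uses average ranks (`scipy.stats.rankdata`) and the
two-sided t approximation p = 2·P(T_{n−2} ≥ |ρ|√((n−2)/(1−ρ²))). An exact
permutation option exists for n ≤ 8 samples; at the survey sizes this
package targets (≥ 200 samples) the t approximation is accurate. OTUs with
zero variance across samples have undefined ρ: they are counted, logged, and
excluded from testing and from the graph. Benjamini–Hochberg runs over the
strict upper triangle only (each pair tested once); adjusted values are
monotone-enforced and capped at 1. An edge requires |ρ| ≥ 0.6 and q < 0.05.
These thresholds are the prevailing convention in the soil co-occurrence
literature; they are parameters, not constants, and the test suite exercises
the calling machinery across thresholds. Negative edges are retained as
ordinary edges for all topology and stability computations, with the signed
ρ stored as an edge attribute.

Island membership of an OTU means non-zero abundance in at least one of the
island's samples, in the processed (rarefied, filtered) table. Induced
subgraphs inherit edge attributes unchanged; nodes left without edges are
dropped, so n counts only connected members — this matters, because the
isolated-node rule is precisely what makes connectance fall and average
degree rise with area when edge density inside the meta-network is roughly
area-invariant.

## Complexity metrics

n, L, average degree 2L/n, and connectance L/n². Connectance deliberately
uses n² (not the combinatorial n(n−1)/2): it is the convention this analysis
family reports, and the integer identity connectance·n² = L is asserted in
tests.

Module detection is Louvain modularity maximization (networkx), unweighted,
with a seed; components are handled natively. Reported M is Newman's Q of
that partition, verified in tests against a naive double-loop recomputation
to 1e−12. Relative modularity standardizes against degree-preserving nulls:
RM = (M_obs − ⟨M_null⟩)/⟨M_null⟩ with 100 Maslov–Sneppen rewired graphs by
default (≥ 10·L successful double-edge swaps each, per-null derived seeds,
detection re-run per null). RM is undefined (NaN, warned, excluded pairwise
from fits) if the null mean is 0.

Zi–Pi roles: Zi is the z-score of a node's within-module degree among its
module's members (population SD; a module whose members all have equal
within-degree gives Zi = 0 — a degenerate module cannot certify a hub).
Pi = 1 − Σ_s (k_is/k_i)². Quadrant thresholds Zi ≥ 2.5 and Pi ≥ 0.62, both
inclusive; keystones are the three non-peripheral quadrants. Whether to
partition per island or inherit the meta-network partition is genuinely
open; the default recomputes the partition per island subnetwork, since
roles are reported per island and a meta-partition can be arbitrarily stale
for a small island's induced graph.

## Stability metrics

Robustness: remove ⌊0.5·n⌋ nodes uniformly at random, count any remaining
node with no surviving neighbor as a secondary extinction, report surviving
proportion of the original n; 999 replicates, mean ± SD. The single-pass
isolation rule is the least-parameterized reading of "remaining taxa"
consistent with secondary loss — an isolated node's removal cannot isolate
others, so no cascade iteration is needed. Abundance-weighted cascades are
out of scope. The removal count uses floor; the replicate engine is one
seeded generator per (island, analysis) pair, so results are independent of
thread scheduling.

Global efficiency E = (2/(n(n−1)))·Σ_{i<j} 1/d_ij with 1/d = 0 for
disconnected pairs, hop-count distances (scipy.sparse.csgraph BFS).
Correlation magnitudes are association strengths, not metric lengths, so
paths are unweighted. Vulnerability V_i = (E − E_−i)/E where E_−i is the
efficiency of the node-deleted graph normalized by its own (n−1)(n−2)/2
pairs; V = max_i V_i. A fixed-n normalization is available by flag; the
reduced form is the default because it makes V_i = 1 exactly when deleting i
disconnects everything, and K_n gives V = 0. V is undefined when E = 0.

Keystone removal: delete all non-peripheral nodes, drop newly isolated
nodes, rerun the robustness simulation on both graphs with independent
replicate streams, compare replicate vectors with a two-sided Welch
(unequal-variance) t-test. Zero keystones is flagged degenerate — "not
significant by construction".

## Area scaling

`nar_fit` is OLS of a per-island metric on log10(area); areas are passed in
m² and transformed inside. Reported: slope, intercept,
adjusted R² = 1 − (1 − R²)(n−1)/(n−2), the slope's two-sided p, and the 95%
confidence band of the conditional mean (statsmodels). Missing values
(e.g. undefined RM) are dropped pairwise with a warning and the island count
reported. p-values are floored at the smallest positive double so perfect
fits stay in (0, 1]. Stability–complexity associations are Spearman ρ with
significance stars (0.05/0.01/0.001), uncorrected across the 2×6 grid by
default to mirror per-panel reporting; a flag applies BH across the grid.

## The synthetic archipelago

The generator emulates a fragmented-landscape soil survey: 28 islands,
areas log-uniform on [1e2, 1e6] m², 10 cores per island (280 samples),
per-sample sequencing depth lognormal (median 10 000, σ = 0.35) so that
rarefaction to 8 000 reads drops a realistic fraction of samples, and a
moisture covariate 6.7–28.7% increasing with log area. Island richness is
S_i = round(c·A_i^z·ε_i) with c = 100, z = 0.25 and a lognormal island
effect ε (σ = 0.1): the scatter makes "the SAR exponent is recovered within
its 95% CI" a calibrated statistical statement (measured coverage ≈ 94/100
seeds) rather than a degenerate fit to rounding error.

The species pool (6× the largest island's richness, i.e. ~19 000 OTUs) has
two occupancy classes. A *core* (3.5% of the pool) carries the survey's
signal: core species are included in island communities with high
probability — rising from ≈ 0.4 on the smallest islands to ≈ 1 on the
largest, which is what propagates area into network size. The rest are
*transients* ("rare biosphere"): inclusion weight 1% of core and a 2.5
ln-unit abundance deficit, so any one island hosts many of them but they are
detected in only a couple of samples and never pass the 12-sample prevalence
filter. This two-class structure is deliberate: a continuum of occupancies
leaves a cohort of species sitting just above the prevalence floor whose few
detections coincide island-wise by chance among millions of pairs, and such
coincidences — not biology — would dominate edge calling.

Co-occurrence signal is a latent-factor (Gaussian copula-like) model. The
pool is partitioned into modules (~15 core species each). Each sample draws
one standard-normal factor per module; a species' log-abundance is
base + λ·s_j·f_m(j) + noise, with loading magnitude λ = 3.5, sign s_j
positive for 80% of species, residual σ = 0.5. Two couplings make the same
factor visible to a rank test on sparse count data:

- *Occupancy*: islands draw species with weight exp(γ·suitability of the
  species' module), γ = 0.35·λ, so module-mates share islands (habitat
  filtering acting on guilds).
- *Capture*: a species present on an island enters any given core with
  marginal probability 0.3 (soil microhabitat patchiness), but the capture
  propensity loads on the same module factor (species-level noise σ = 2), so
  module-mates co-occur at the sample level too — locally favoured species
  are the ones a core picks up.

Both couplings are proportional to `factor_strength`; setting it to 0
removes abundance correlation, occupancy clustering and capture correlation
at once, leaving exchangeable presence patterns. The per-core patchiness is
not decoration: with all-or-nothing within-island presence, 10 cores per
island replicate each island footprint tenfold, and chance footprint
coincidences between species masquerade as correlations near |ρ| ≈ 1. At
capture 0.3, measured across seeds, the zero-signal archipelago yields zero
called edges in most seeds and no significant link–area slope.

What the generator does *not* emulate: taxonomy and phylogeny, true
interaction topology (the "modules" are statistical guilds), compositional
bias of amplicon protocols, spatial autocorrelation within islands, and any
temporal dynamics. Passing tests on this generator therefore demonstrates
that the pipeline detects planted rank-correlation structure and its area
scaling without fabricating either from survey geometry — not that any
particular empirical system behaves like the model.

Fixtures: `generate_fixture("tiny")` (3 islands, ~36-OTU pool),
`"modular"` (24 samples × 20 OTUs in 4 blocks with within-block |ρ| ≥ 0.8 by
construction, asserted at generation), and `"star-stability"` (named small
graphs — star, path, cliques, two triangles, small ER graphs, and a planted
hub-and-spoke modular graph whose 4 hubs are keystones).

## Numerical and reproducibility conventions

- Every stochastic step takes an explicit seed; derived seeds use
  `np.random.default_rng([master, tag, index])` so per-sample rarefaction and
  per-island analyses are independent of ordering and of the thread count.
  Two runs with one config are byte-identical, including with
  `threads=4` vs `1` (asserted in tests).
- Rarefaction is a multivariate hypergeometric draw (classic
  without-replacement rarefaction); samples below depth are dropped, not
  padded, with a logged list.
- Degenerate inputs: empty islands are flagged and excluded pairwise;
  reps = 1 robustness reports SD as NaN with a warning; E = 0 graphs have
  undefined vulnerability; a null ensemble with zero mean modularity yields
  NaN RM.
- Ties in Spearman use average ranks throughout; BH uses a stable mergesort
  so equal p-values adjust deterministically.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the generator at its default
(28 islands × 10 samples) scale. Monte-Carlo robustness uses the default 999
replicates. Relative-modularity null ensembles use 20–50 rewired graphs in
the shipped end-to-end runs and 10 in unit tests (the estimator's default
remains 100); multi-seed recovery checks use 20 seeds. These sizes are the
package's own choices for routine verification; all are parameters.

## Known limitations

- Spearman on compositional counts can induce spurious negative dependence;
  no compositionality-aware estimator (SparCC/SPIEC-EASI style) is included,
  by design — the pipeline implements the plain-correlation workflow and
  accepts externally filtered edge lists through `edge_list`.
- Indirect-association removal is a hook, not an implementation.
- The vulnerability computation is exact and therefore O(n) all-pairs BFS
  passes per network; for subnetworks beyond ~5 000 nodes it becomes the
  dominant cost.
- Louvain is resolution-1 only; the partition method is pluggable but no
  alternative is bundled.
- The keystone-removal contrast compares Monte-Carlo replicate vectors, so
  its t-test p-value scales with the replicate count; it should be read as
  an effect-size screen, not a calibrated hypothesis test.
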