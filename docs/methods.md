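# Methods

This note documents the models, estimators and numerical choices behind
`fracnet`, and what the synthetic-data generator does and does not
emulate.

## Data model and containers

An `AsvTable` is a samples × ASVs matrix of non-negative counts (or
relative abundances) for one size fraction, with per-sample metadata
(season ∈ {winter, spring, summer, autumn}, layer, station) and
per-ASV annotation (taxonomy lineage; for protists a trophic mode in
{photoautotroph, heterotroph, mixotroph, symbiont, parasite, unknown}).
Relative-abundance conversion leaves all-zero samples all-zero and
records them; downstream stages warn rather than fail on them.

## Cross-fraction deduplication

Sequential size filtration leaks cells between fractions (dislodging,
clogging), so the same ASV can appear in both protist tables. For each
shared ASV the ratio of mean relative abundance, r = n̄/p̄ computed
over all samples, decides the action: r > 2 removes the ASV from the
pico table, r < 0.5 from the nano table, boundary values stay (strict
inequalities). A pico mean of zero with a positive nano mean is
treated as r = +∞. The per-sample variant of the ratio is not well
defined when an ASV is absent from a sample, which is why the
across-sample mean is used; the report records the basis so audits can
recompute alternatives. The operation is idempotent.

Network-eligible ASVs are those present in every season, in strictly
more than one third of samples, and with mean relative abundance
strictly greater than 0.001. Selection does not renormalize the
surviving columns: the thresholds refer to abundances relative to the
original community, and renormalizing would make the filter
non-idempotent.

## Diversity and permutation tests

Shannon entropy uses the natural logarithm. Chao1 defaults to the
bias-corrected estimator S₁ = S_obs + F₁(F₁−1)/(2(F₂+1)), which is
defined when no doubletons exist; the classic F₁²/(2F₂) form is behind
a flag. Pielou's J = H/ln S_obs is reported as missing for samples
with fewer than two observed ASVs.

Bray–Curtis dissimilarities are computed on Hellinger-transformed
abundances for ordination and testing. NMDS minimizes Kruskal
stress-1 by SMACOF majorization with isotonic regression of embedding
distances on the rank order of the observed dissimilarities; the first
start is classical MDS and the remaining starts are random, best
configuration kept. Stress is non-increasing across iterations by
construction of the Guttman transform.

PERMANOVA uses the squared-distance decomposition: SS_total =
Σ_{i<j} d²ᵢⱼ/n, SS_within summed per group, pseudo-F =
(SS_between/(g−1))/(SS_within/(n−g)), with free permutation of group
labels (single-factor design, no strata). Mantel statistics correlate
upper-triangle entries (Spearman by default, Pearson optional); the
partial Mantel uses the first-order partial correlation
r₁₂·₃ = (r₁₂ − r₁₃r₂₃)/√((1−r₁₃²)(1−r₂₃²)) and permutes only the first
matrix. All permutation p-values use the add-one rule
p = (1 + #{perm ≥ obs})/(1 + n_perm), so p ∈ (0, 1] and a seed makes
them reproducible. Correlation matrices against environmental
variables are Benjamini–Hochberg adjusted.

## Levins' niche breadth

Within a metacommunity of N communities (by default the samples of one
season, across layers and stations), P_ij is the share of ASV j's
metacommunity total found in community i and B_j = 1/Σᵢ P²ᵢⱼ ∈ [1, N].
B is invariant to rescaling an ASV's abundances and to community
order. The community-level index is the unweighted mean of B_j over
ASVs with non-zero abundance in that sample ("taxa within a
community"); an abundance-weighted mean is available behind a flag.
No rare-ASV filtering is applied by default — the network-selection
filter can be applied upstream when a filtered variant is wanted.

## Network inference

Counts are mapped to the real line by a modified centered log-ratio:
non-zero entries are log-transformed and centered by the geometric
mean of the row's non-zero entries; zeros stay zero. This avoids an
arbitrary pseudocount while keeping per-sample scale invariance.

The conditional-dependence graph is estimated by neighborhood
selection: each column is lasso-regressed on all others (cyclic
coordinate descent, via scikit-learn) over a geometric penalty path of
20 values from λ_max (the largest absolute cross-covariance of the
standardized data, at which every neighborhood is empty) down to
λ_max/200. StARS draws 20 subsamples of size min(⌊10√n⌋, ⌊0.8 n⌋)
without replacement, measures per-edge selection frequencies ξ and the
per-λ instability D = mean 2ξ(1−ξ), monotonizes D along decreasing λ,
and selects the smallest λ whose monotonized instability stays ≤ 0.05
— the densest graph that is still stable. If no λ qualifies the
sparsest graph is returned with a warning flag. The final network is
the full-data fit at λ*, symmetrized with the OR rule (an edge exists
if either directed coefficient is non-zero; the larger-magnitude
coefficient, sign preserved, is the weight). The OR rule keeps more
interdomain edges; AND is behind a flag. Sparse + low-rank variants
that absorb latent confounders are a possible extension point; the
`method` field of every network records `mb-stars` so downstream
consumers know which estimator produced it.

## Network analysis

Edge weights are association strengths, not lengths, so all paths are
unweighted, and modularity/community detection likewise runs on the
unweighted topology (signed weights are not valid modularity
weights). Reported metrics: Louvain modularity (best of 10 seeded
restarts, resolution 1), average shortest-path length over connected
pairs, average degree 2E/N, diameter (largest finite eccentricity),
density, mean local clustering, Freeman degree centralization
Σ(k_max−k_i)/((N−1)(N−2)), and a small-world index
(C/C_rand)/(L/L_rand) against 20 seeded Erdős–Rényi G(N, E) graphs.
Small-world magnitudes depend strongly on the null-model convention;
the convention used here is recorded with the output rather than
matched to any particular published scale.

Keystone nodes are those in the top 20% of both degree and betweenness
centrality. Percentiles are taken over the distinct values of each
centrality (dense rank, nearest-rank cutoff, ties inclusive): a
regular ring — where every node ties — returns all nodes, while a
star returns only its hub. Rank over raw values would let a tie at
the cutoff flood the keystone set in small or degree-degenerate
graphs.

Random-attack robustness removes nodes one at a time in a uniformly
random order; after the i-th removal σᵢ is the largest-component size
divided by the original N, and R = (1/N)Σᵢσᵢ averaged over iterations
(10,000 by default), V = 0.5 − R exactly. The published formula for R
is typographically garbled at the source; the implementation follows
the standard normalized attack robustness of the methodology
literature, which reproduces the closed form R = (N−1)/(2N) on
complete graphs. The Monte-Carlo kernel adds nodes back in reverse
order under a union-find, so one iteration costs O(N + E α(N));
iterations are batched through a numba-compiled kernel.

Nodal efficiency of node i is (1/(N−1))Σ_{j≠i} 1/d_ij with 1/∞ = 0 for
unreachable pairs; global efficiency is the mean over ordered pairs.
Distributions are reported sorted ascending with mean μ and standard
deviation σ.

## Biomass and PPBR

Carbon conversion uses per-cell factors HB 20, Syn 178, PPE 1500 and
HNF/PNF 4700 fg C cell⁻¹ (one nanoflagellate factor for both HNF and
PNF); all factors are configurable. PPBR is the biomass ratio HNF/HB
and HNF/PPE, log₁₀-transformed; zero prey biomass yields a missing
value and the sample is flagged. PPBR is invariant to a common
rescaling of all abundances.

## PLS path modeling

The inner model is recursive (lower-triangular adjacency over the
latent order); all blocks are reflective (mode A), since indicator
loadings are treated as substantively meaningful. Estimation follows
Lohmöller's alternating scheme: standardized indicators, outer proxies
from current weights, inner proxies by the chosen scheme (path
weighting by default: regression weights toward predecessors,
correlations toward successors; centroid and factor available), mode-A
weight update w ∝ cov(x, inner proxy), iterated until the largest
weight change falls below 1e-8 (error on non-convergence). Latent
scores are standardized after every update; each latent is oriented so
its mean loading is positive. Path coefficients are OLS regressions
of each endogenous score on its predecessors; loadings are
indicator–score correlations; gof = √(mean communality × mean R² over
endogenous latents). Total effects are Σ_k Bᵏ over the coefficient
matrix (finite by acyclicity); indirect = total − direct.

Indicators with |loading| < 0.7 are pruned and the model refit until
all survive or a block would empty (an error naming the block — the
pipeline falls back to the unpruned fit with a warning in that case).
Bootstrap CIs are percentile intervals from row resampling (1,000
replicates by default); degenerate resamples are skipped and counted.
With single-indicator blocks the whole procedure collapses to
standardized OLS path analysis, which the tests exploit as an exact
oracle. Mode-A composites attenuate structural coefficients by the
square of the composite–latent correlation (≈ 0.94 for four
indicators loading 0.9), which bounds the accuracy achievable in
recovery tests.

In the pipeline, network robustness and efficiency exist once per
seasonal network; they are broadcast to the samples of that season to
join the per-sample indicator table, and the fit metadata records
this.

## Synthetic data

The generator emulates what a seasonal survey delivers after sequence
processing, with ground truth for every downstream claim:

- **Counts** follow a logistic-normal-multinomial: latent
  log-abundances of the "core" (network-eligible) ASVs of all three
  fractions are multivariate normal with covariance Ω⁻¹ for a known
  sparse positive-definite precision matrix Ω, whose off-diagonal
  support is the ground-truth edge set. The default random Ω has
  expected degree ≈ 3 (edge probability 0.05 at p = 60), matching the
  sparse topology typical of amplicon co-occurrence networks, with
  partial-correlation weights 0.35 before diagonal dominance. Core
  ASVs carry a mean advantage (+2 on the log scale) so they pass the
  prevalence and abundance screens; each fraction also carries rare
  background ASVs (latent mean −4.5, sd 2.0) that the screens should
  discard. Per sample the fraction's latent vector is softmaxed and
  counts drawn from a multinomial at the sequencing depth (default
  20,000 reads), then thinned by Bernoulli zero-inflation (default
  0.02).
- **Environment**: Gaussian noise around season-specific means for
  temperature, salinity, DO, TN, TP, resembling a subtropical
  eutrophic bay; a single `season_effect` factor scales all seasonal
  contrasts (0 gives an exact null, used by calibration tests).
- **Cytometry**: log-normal abundances around season-dependent log₁₀
  means for HB, Syn, PPE, HNF, PNF; strictly positive.
- **Contamination**: prescribed pico-ASVs are copied into the nano
  table at counts solving s = r̄·T/(1 − r̄) so the realized
  nano/pico mean-relative-abundance ratio equals the requested target
  after the new column inflates the row totals — copy-based so the
  ratio is exactly controllable.
- **Latent path data**: recursive structural equations with residual
  variances topping each latent up to 1; indicators are
  loading × latent + √(1−loading²) × noise, standardized in
  expectation. Used for PLS-PM ground-truth recovery.

The default scenario is 4 seasons × 10 samples with 20 core + 40
background ASVs per fraction. Seasons are categorical labels on
blocks of samples: no temporal autocorrelation, no coupling between
the environmental gradients and the count table, no read-level
artifacts (chimeras, taxonomy error), and no spatial structure. Tests
passing on these data therefore demonstrate correctness of the
estimators and calibration of the tests under the generator's
assumptions — not that real communities satisfy those assumptions. In
particular, at 40 samples the StARS network recovers the generating
edge set with high precision but low recall (stability selection at
the 0.05 instability target is deliberately conservative); recall
rises steadily with sample size, which the test suite asserts on
latent-scale data at n ∈ {100, 400, 1600}.

## Problem sizes and determinism

Default problem sizes (40 samples, ~60 network ASVs, 10,000 robustness
iterations, 1,000 bootstraps, 999 permutations) run the full pipeline
in about a minute on one CPU. Calibration tests use 200–500 replicates
with 199 permutations or bootstrap draws, which keeps their
Monte-Carlo error well inside the asserted bands. Every stochastic
component takes an explicit seed; the pipeline derives stage seeds
from the global seed via `numpy.random.SeedSequence`, and the run
manifest records output checksums so end-to-end determinism is
verifiable.

## Known limitations

- The latent-variable (sparse + low-rank) refinement of the network
  estimator is not implemented; confounding environmental gradients
  can induce spurious edges that MB + StARS will keep.
- Robustness and efficiency treat the graph as unweighted and
  undirected; weighted or directed generalizations are out of scope.
- The PLS-PM broadcast of network-level quantities to samples reuses
  one value per season, so its bootstrap CIs understate the
  uncertainty contributed by network inference itself.
- Chao1 requires integer counts and is undefined on relative tables.
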