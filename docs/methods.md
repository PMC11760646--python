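# Methods

This note documents the statistical model implemented by `sbmmrf`, its
tunable parameters, the numerical choices made where the design was open,
and what the simulation-based tests do and do not establish.

## Data preparation

**Compositions and the MCLR transform.** Counts are row-normalized to
compositions; the modified centered-log-ratio transform is applied per
sample to the non-zero entries only, using the geometric mean of the
sample's non-zero compositions (computed as the mean of logs to avoid
under/overflow). Two modes are provided:

- `robust_clr` (`ε_i = 0`): non-zero entries of each row are centered in
  log space and sum to zero.
- `shifted` (default): `ε_i = 1 + |min_j log(x_ij/g̃(x_i))|` is added per
  row, making every transformed non-zero strictly positive so that the
  value 0 unambiguously encodes absence.

Zeros are never imputed — pseudo-count CLR disguises absent taxa and can
induce spurious correlations, which is precisely what the MCLR avoids.
Taxa can be prevalence-filtered before transformation (`min_nonzero`,
default 1 = no filtering; a threshold around 7 non-zero samples is common
for species-level tables but is dataset-specific, so it is a parameter,
not a constant). The per-row shift is recomputed from whatever matrix is
passed in, so re-running the pipeline after filtering recomputes `ε_i`
from the filtered data.

**Network estimation.** Spearman rank correlation (average ranks for ties
— the zero-inflated transform produces massive ties at zero) is computed
for all column pairs. Two-sided p-values use the t approximation
`t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom, the standard test for
H₀: ρ = 0; |ρ| = 1 maps to p = 0, and constant columns (undefined rank
correlation) are reported as ρ = 0, p = 1 with a warning. The
Benjamini–Hochberg step-up adjustment is applied jointly to the
p(p−1)/2 distinct pairs only — adjusting the full symmetric matrix would
double-count every test. An edge requires the adjusted p-value to be
*strictly below* α (default 0.05), so `p_adj = α` yields no edge and
α = 0 yields the empty network.

**Same-parent matrix.** `Q` encodes one parent level only (genus for
species-level data); using ranks higher up the tree makes nearly all taxa
neighbors and collapses the prior's information. Taxa missing from the
taxonomy receive unique singleton parents (all-zero rows of `Q`), so
incomplete annotation degrades gracefully to non-informativeness.

## Model and inference

**Likelihood.** Conditional on labels `z` and block probabilities `Ω`,
edges are independent Bernoulli draws with probability `ω_{z_j z_j'}`.
Sufficient statistics are the observed (`M`) and possible (`N`) edge
counts per unordered block pair. The log-likelihood uses the
`0·log 0 = 0` convention so boundary blocks are handled exactly.

**Priors.** Independent Beta(a_ω, b_ω) on each `ω_kk'` (default
a_ω = b_ω = 1, the non-informative choice), conjugate to the Bernoulli
likelihood. Labels carry a Markov random field prior on the same-parent
graph with conditionals
`p(z_j = k | z_−j, Q) ∝ exp(e_k + d·s_jk)` where `s_jk` counts j's
same-parent neighbors currently in community k. Base rates default to
`e_k = log(1/K)`; at `d = 0` the prior is discrete uniform and the model
is exactly the taxonomy-free Bayesian SBM (asserted numerically in the
tests). `d` is a fixed hyperparameter, not inferred; `d = 1` is the
default — large couplings push the field through a phase transition in
which labels collapse along the parent cliques regardless of the network.

**Gibbs sampler.** Labels are initialized uniformly at random (seeded).
Each iteration (i) sweeps taxa in ascending index order, drawing each
`z_j` from its full conditional given the partially updated labels and
current `Ω`; (ii) recomputes `M`, `N` and redraws `Ω` from its beta
conditional (empty blocks draw from the prior); (iii) relabels
communities by decreasing intra-block edge probability (stable ties) and
records the state. Per-candidate label evaluation uses the exact
incremental form — only pairs incident to the updated taxon change, so
the candidate scores reduce to `Σ_k' [r_k' log ω_kk' + (t_k' − r_k')
log(1−ω_kk')]` with `r` = neighbor counts and `t` = community sizes
excluding the taxon — which equals the full-likelihood difference to
machine precision (tested against brute-force recomputation). All
computation is in the log domain with max-subtraction before
normalization; sampled `Ω` entries are clipped away from {0, 1} only
inside logs. Identical seed and configuration reproduce chains bit for
bit.

**Annealed coupling (design choice).** In strong-taxonomy regimes at
small K, parent cliques reach the size of whole communities (~50–60
taxa), so the MRF conditional carries logits of order `d·50`. The first
few sweeps then act at full coupling before the likelihood has localized
the block structure, and whatever label field they produce — including
states where two parent cliques share one label — is frozen; such merged
states are genuine deep local modes that single-site moves cannot leave
(measured: at K=3, p=180, strong taxonomy, d=1, T=500, 6 of 8 chains
ended at ARI ≈ 0.56 instead of ≈ 1). The sampler therefore ramps the
coupling linearly from 0 to `d` over the burn-in phase
(`GibbsConfig.anneal_mrf`, default on): exploration is likelihood-driven
first and the taxonomy prior then reinforces and refines the partition.
All post-burn-in transitions use the full coupling, so recorded
inference targets the exact posterior; the small-instance
enumerated-posterior test validates the unannealed kernel directly. A
`d = 0` run is unaffected, keeping sensitivity comparisons between
`d = 0` and `d > 0` meaningful.

**Posterior summaries.** `Ω̂` is the element-wise posterior mean over
post-burn-in draws. `ẑ` is the stored post-burn-in sample maximizing the
log unnormalized posterior; because the MRF's global normalizing constant
is intractable, the label-prior term is the pseudo-likelihood
`Σ_j log p(z_j | z_−j, Q)` built from the MRF conditionals — computable,
exact at `d = 0`, and monotone in the same neighbor-agreement statistic
the prior rewards. Ties go to the earliest iteration.

**Model selection.** `BIC = ν log p − 2 log f(G | ẑ, Ω̂)` with
`ν = p + K(K+1)/2` (p labels plus K(K+1)/2 block probabilities). The
likelihood term is the network likelihood only: `Q` is conditioning
information with no generative model attached, so it contributes no
likelihood by default (an `include_prior` flag adds the pseudo-prior term
for users who want the joint score). `select_k` fits every K on its own
derived seed and returns both the scree table and the BIC minimizer —
the minimum is the default choice, but the table is always emitted
because elbow-based overrides are common and legitimate. Convergence is
assessed by the pairwise ARI of MAP partitions across independently
initialized chains.

## Synthetic data

The simulator draws from the stochastic block model itself: p taxa
(default 180) split evenly over K communities (remainder to the last);
intra-community edge probabilities take preset vectors spanning sparse to
near-clique blocks — (0.3, 0.6, 0.95) for K=3, (0.1, 0.3, 0.5, 0.7, 0.9,
0.97) for K=6, (0.12, 0.2, 0.3, 0.4, 0.5, 0.7, 0.8, 0.9, 0.99) for K=9,
(0.1, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.97) for
K=12 — inter-community probabilities are drawn once per community pair
from Uniform(0, 0.1), and each unordered pair's edge is an independent
Bernoulli draw.

Genus labels (30 genera by default) are generated so that
ARI(community, genus) lands in a configured informativeness band: weak
(≤ 0.3), moderate (0.3, 0.7], strong (0.7, 1]. The generator starts from
perfect alignment (one genus per community; surplus genera empty, which
is permitted) and degrades it by moving uniformly chosen taxa to
uniformly chosen genera until the ARI reaches a target drawn inside the
band; the achieved ARI is recorded per dataset. Single-taxon moves change
ARI by O(1/p), so bands are entered rather than jumped over; the walk
restarts if it exits below the band and fails loudly if the band is
unreachable within a bounded step count. In weak mode the degradation
target defaults to ≤ 0.1, keeping achieved values well clear of the 0.3
boundary. Note a structural fact, not an implementation choice: at small
K a high band forces a few dominant genera of roughly community size,
because a fine nested partition of each community cannot exceed moderate
ARI against the coarse community partition.

Replicates (default 50) derive per-dataset seeds from the master seed
plus the setting (K, strength, replicate), so full grids are reproducible
and distinct.

**What the simulations do not emulate.** Data are generated at the
network level — exactly the model the SBM assumes — so recovery results
validate the inference machinery, not the first-stage network estimation
on real sequencing data. Real co-occurrence networks carry correlated
test errors, compositional artifacts and sampling-depth effects that no
block model generates; passing the recovery tests shows the sampler finds
planted structure, not that species interactions are correctly inferred
from counts. The count-level pipeline is exercised end-to-end only as a
smoke test.

## Evaluation

The adjusted Rand index is implemented from unordered pair counts
(a, b, c, d): `ARI = [C(p,2)(a+d) − T] / [C(p,2)² − T]` with
`T = (a+b)(a+c) + (c+d)(b+d)`, computed via the contingency table in
O(p + K₁K₂). A zero denominator occurs only when both partitions are the
same trivial partition, where 1.0 is returned. The implementation is
cross-validated in the tests against the Hubert–Arabie contingency-table
form (scikit-learn) to 1e-10, including by exhaustive enumeration of all
partitions of 6 items into ≤ 3 blocks. The sensitivity harness refits
every simulated dataset at each coupling in a `d` grid (seeds derived per
replicate × d), records ARI(truth, ẑ), and compares `d = 0` against each
`d > 0` by paired Wilcoxon signed-rank tests (scipy); identical ARI
vectors short-circuit to p = 1. External methods are compared by
ingesting their label files and scoring the same ARI — no competitor is
re-implemented.

## Problem sizes used in the test suite

Unit tests run on instances of a few dozen taxa. The validation suite
uses: 10,000 label pairs at p=200 for the ARI null; a p=8, K=2 instance
with 30,000 sweeps against the exhaustively enumerated
(beta-marginalized) posterior, with relabeling and annealing disabled so
the raw kernel is what is checked (total variation ≤ 0.05 over the 256
configurations); 10 replicates at K=3, p=180 and 8 at K=6, p=180 with
T=500 for parameter recovery; and a p=90 planted 3-block graph with
T=400 per K for BIC selection. These sizes were chosen so the whole suite
completes in a couple of minutes while keeping Monte-Carlo margins wide.

## Known limitations

- `K` is fixed per fit; no split/merge moves, so empty communities can
  persist and model selection requires a scan over K.
- No degree correction or mixed membership; heterogeneous degrees within
  a community are attributed to noise.
- The MAP/BIC label-prior term is a pseudo-likelihood, not the exact MRF
  normalizing constant (exact at d = 0).
- Single-site Gibbs mixes slowly between well-separated modes; the
  annealed coupling addresses the dominant failure mode, but multi-chain
  agreement should still be checked (`chain_agreement`).
- Stage 1 treats the estimated network as fixed truth downstream; edge
  uncertainty does not propagate into the block model.
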