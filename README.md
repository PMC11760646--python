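# sbmmrf

Taxonomy-aware Bayesian stochastic block models for microbiome
co-occurrence networks.

## The problem

Shotgun metagenomics yields a count table `Y` (n samples × p taxa) that is
compositional, over-dispersed and riddled with zeros. A central question
for microbiome ecology is which taxa form **communities**: groups that
co-occur densely with each other and sparsely with everyone else, since
such groups often share metabolic function and track dysbiosis. `sbmmrf`
implements a two-stage pipeline for this, aimed at statisticians and
bioinformaticians analyzing species-level abundance tables:

**Stage 1 — network estimation.** Counts are row-normalized to
compositions `X` and transformed with the modified centered-log-ratio
(MCLR), which transforms only the non-zero part of each sample,

    v_ij = 0                          if x_ij = 0
    v_ij = log(x_ij / g̃(x_i)) + ε_i   if x_ij > 0

where `g̃(x_i)` is the geometric mean of the sample's non-zero
compositions and `ε_i = 1 + |min_j log(x_ij/g̃(x_i))|` keeps transformed
non-zeros strictly positive (with `ε_i = 0` this is the robust CLR). No
pseudo-counts: zeros stay zero. Pairwise Spearman correlations of the
transformed columns are tested against ρ = 0, Benjamini–Hochberg adjusted
over the p(p−1)/2 pairs, and thresholded at α = 0.05 into a binary
co-occurrence network `G`.

**Stage 2 — community detection.** `G` is modeled by a stochastic block
model with a fixed number of communities `K`: labels `z ∈ {1..K}^p`, block
edge probabilities `Ω ∈ [0,1]^{K×K}`, and likelihood

    f(G | z, Ω) = ∏_{k≤k′} ω_kk′^{M_kk′} (1 − ω_kk′)^{N_kk′ − M_kk′}

with conjugate Beta(a_ω, b_ω) priors on each `ω_kk′`. The label prior is a
Markov random field on the **same-parent matrix** `Q` of the taxonomic
tree (`q_jj′ = 1` when two species share a genus):

    p(z_j = k | z_−j, Q) ∝ exp( e_k + d · #{same-parent neighbors of j in community k} )

so related species are encouraged, with strength `d ≥ 0`, to share a
community. At `d = 0` this is exactly the standard Bayesian SBM with a
uniform label prior. Inference is a two-step Gibbs sampler (label sweep,
then conjugate beta draws for `Ω`), with per-iteration relabeling by
decreasing intra-block edge probability to fix label switching. Posterior
summaries are the element-wise posterior mean `Ω̂` and the MAP label vector
`ẑ`; the number of communities is chosen by minimizing
`BIC = ν log p − 2 log f(G | ẑ, Ω̂)` with `ν = p + K(K+1)/2`.

The package also ships the full validation harness: a generative simulator
for block networks with genus labels of controlled informativeness
(banded by the adjusted Rand index between genus and community labels),
the pair-count ARI statistic itself, and a sensitivity study over `d`
with paired Wilcoxon tests.

## Worked example

Simulate a 3-community network of 90 taxa (intra-community edge
probabilities 0.3 / 0.6 / 0.95, inter-community probabilities drawn from
Uniform(0, 0.1), strongly informative genus labels), then fit with `d = 1`:

```python
import numpy as np
from sbmmrf import (SimulationConfig, GibbsConfig, MRFPrior, run_gibbs,
                    fit_summary, select_k, ari)
from sbmmrf.simulate import generate_dataset

ds = generate_dataset(SimulationConfig(K=3, p=90, strength="strong", seed=42), 0)
chain = run_gibbs(ds.G, ds.Q, K=3, prior=MRFPrior(d=1.0),
                  config=GibbsConfig(n_iter=500, seed=7))
summ = fit_summary(chain, ds.G)
print("ARI(truth, z_map):", round(ari(ds.z_true, summ.z_map), 3))
print("community sizes:", np.bincount(summ.z_map).tolist())
print("omega_hat diag:", np.round(np.diag(summ.omega_hat), 3).tolist())
```

prints

```
ARI(truth, z_map): 1.0
community sizes: [30, 30, 30]
omega_hat diag: [0.946, 0.625, 0.272]
```

— the planted partition is recovered exactly (ARI 1), and the estimated
intra-community edge probabilities match the generating values
(0.95 / 0.6 / 0.3; communities are reported in decreasing density order).
Scanning `K` with `select_k(ds.G, ds.Q, range(1, 7), ...)` returns the BIC
table and picks `K = 3`, the planted number of communities.

The same workflow is available from the shell:

```sh
sbmmrf transform --input counts.tsv --out V.tsv --min-nonzero 7
sbmmrf network --input V.tsv --alpha 0.05 --out-adjacency G.tsv --out-stats stats.tsv
sbmmrf fit --adjacency G.tsv --taxonomy tax.tsv --k 7 --d 1.0 --iters 1000 --seed 1 --out chain/
sbmmrf summarize --chain chain/ --adjacency G.tsv --out summary.json --heatmap heatmap.png
sbmmrf select-k --adjacency G.tsv --taxonomy tax.tsv --kmin 2 --kmax 10 --out scan/
```

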