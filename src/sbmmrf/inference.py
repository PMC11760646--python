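"""Posterior summaries, BIC-based selection of K, and convergence diagnostics.

Point estimates follow standard practice for block models fit by MCMC: the
edge-probability matrix is summarized by its element-wise posterior mean
over post-burn-in draws, and the label vector by the stored sample with
the highest (unnormalized) log posterior — the MAP over visited states.
The number of communities is chosen by minimizing

    BIC = nu * log(p) - 2 * log f(G | z_hat, Omega_hat),   nu = p + K(K+1)/2

over a grid of K; a scree table is always returned because elbows are often
more informative than the global minimum. Agreement between independent
chains is quantified by the adjusted Rand index of their MAP partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import derived_seed as _derived_seed
from .metrics import ari
from .sbm import (
    GibbsConfig,
    MRFPrior,
    PosteriorChain,
    _as_adjacency,
    _as_q,
    _log_pseudo_prior,
    log_likelihood,
    run_gibbs,
)


@dataclass
class FitSummary:
    """Point estimates and model-selection statistics for one fitted K."""

    z_map: np.ndarray
    omega_hat: np.ndarray
    bic: float
    K: int
    n_params: int
    map_iteration: int
    log_lik: float


def posterior_mean_omega(chain: PosteriorChain) -> np.ndarray:
    """Element-wise posterior mean of Omega over post-burn-in samples."""
    return chain.omega_samples[chain.burn_in:].mean(axis=0)


def map_estimate(chain: PosteriorChain) -> tuple[np.ndarray, int]:
    """Post-burn-in sample with the largest stored log posterior.

    Returns the label vector and the (0-based) iteration index; ties go to
    the earliest iteration.
    """
    B = chain.burn_in
    t = int(np.argmax(chain.log_post[B:])) + B
    return chain.z_samples[t].copy(), t


def compute_bic(G, z_hat: np.ndarray, omega_hat: np.ndarray, K: int,
                Q=None, prior: MRFPrior | None = None,
                include_prior: bool = False) -> tuple[float, int]:
    """BIC = nu log p - 2 loglik with nu = p + K(K+1)/2.

    The likelihood term is the network likelihood ``log f(G | z, Omega)``
    by default; ``include_prior=True`` adds the MRF pseudo-prior of the
    labels given the same-parent matrix.
    """
    A = _as_adjacency(G)
    p = A.shape[0]
    nu = p + K * (K + 1) // 2
    loglik = log_likelihood(A, z_hat, omega_hat)
    if include_prior:
        if Q is None or prior is None:
            raise ValueError("include_prior requires Q and prior")
        loglik += _log_pseudo_prior(np.asarray(z_hat, np.int64), _as_q(Q), prior, K)
    return nu * np.log(p) - 2.0 * loglik, nu


def fit_summary(chain: PosteriorChain, G, Q=None,
                prior: MRFPrior | None = None) -> FitSummary:
    """Bundle MAP labels, posterior-mean Omega and BIC for a fitted chain."""
    z_map, t = map_estimate(chain)
    omega_hat = posterior_mean_omega(chain)
    A = _as_adjacency(G)
    loglik = log_likelihood(A, z_map, omega_hat)
    bic, nu = compute_bic(A, z_map, omega_hat, chain.K)
    return FitSummary(z_map, omega_hat, float(bic), chain.K, nu, t, float(loglik))


def select_k(G, Q, k_grid: Sequence[int], prior: MRFPrior | None = None,
             config: GibbsConfig | None = None) -> tuple[pd.DataFrame, int]:
    """Fit the model for every K in the grid and pick the BIC minimizer.

    Each K runs its own chain with a seed derived from the master seed, so
    the whole scan is reproducible. Returns the scree table (K, bic, nu,
    loglik, map_iteration) sorted by K and the selected K.
    """
    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    prior = prior if prior is not None else MRFPrior()
    config = config if config is not None else GibbsConfig()
    rows = []
    for K in sorted(k_grid):
        cfg = GibbsConfig(
            n_iter=config.n_iter, burn_in=config.burn_in,
            a_omega=config.a_omega, b_omega=config.b_omega,
            seed=_derived_seed(config.seed, K), relabel=config.relabel,
        )
        chain = run_gibbs(G, Q, K, prior=prior, config=cfg)
        summ = fit_summary(chain, G)
        rows.append({"K": K, "bic": summ.bic, "nu": summ.n_params,
                     "loglik": summ.log_lik, "map_iteration": summ.map_iteration})
    table = pd.DataFrame(rows).sort_values("K").reset_index(drop=True)
    best_k = int(table.loc[table["bic"].idxmin(), "K"])
    return table, best_k


def chain_agreement(chains: Sequence[PosteriorChain]) -> tuple[np.ndarray, dict]:
    """Pairwise ARI between the MAP partitions of parallel chains.

    High agreement (near 1) across chains started from independent random
    label initializations is the convergence check used in practice.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    p = chains[0].n_taxa
    if any(c.n_taxa != p for c in chains):
        raise ValueError("chains disagree on the number of taxa")
    maps = [map_estimate(c)[0] for c in chains]
    m = len(maps)
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = ari(maps[i], maps[j])
    iu = np.triu_indices(m, k=1)
    vals = mat[iu]
    summary = {"min": float(vals.min()), "mean": float(vals.mean()),
               "max": float(vals.max())}
    return mat, summary


def degree_table(G, z: np.ndarray) -> pd.DataFrame:
    """Per-taxon nodal degree, within its community and across the network.

    Nodal degree in an undirected binary network is simply the number of
    incident edges; the intra-community column counts only edges to taxa
    sharing the node's community label.
    """
    A = _as_adjacency(G)
    z = np.asarray(z, dtype=np.int64)
    same = (z[:, None] == z[None, :]).astype(np.int8)
    intra = (A * same).sum(axis=1)
    total = A.sum(axis=1)
    ids = G.taxon_ids if hasattr(G, "taxon_ids") else [str(i) for i in range(A.shape[0])]
    return pd.DataFrame({
        "taxon_id": ids,
        "community": z + 1,  # 1-based for reporting
        "intra_community_degree": intra,
        "intra_network_degree": total,
    })
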