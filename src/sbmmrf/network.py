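"""Binary co-occurrence network estimation via Spearman correlation with FDR control.

Pairwise monotone association between MCLR-transformed taxa is measured by
the Spearman rank correlation (average ranks for ties — zero-inflated
transforms produce massive ties at zero). Two-sided p-values come from the
t approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` with ``n - 2``
degrees of freedom, are Benjamini-Hochberg adjusted over the p(p-1)/2
distinct pairs, and an edge is assigned wherever the adjusted p-value is
strictly below the significance level ``alpha`` (default 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import TransformedMatrix

logger = logging.getLogger(__name__)


@dataclass
class Network:
    """Symmetric binary adjacency with optional correlation / p-value layers."""

    adjacency: np.ndarray
    taxon_ids: list[str]
    rho: np.ndarray | None = None
    p_raw: np.ndarray | None = None
    p_adj: np.ndarray | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any((A != 0) & (A != 1)):
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        self.adjacency = A.astype(np.int8)
        if len(self.taxon_ids) != A.shape[0]:
            raise ValueError("taxon_ids length does not match adjacency")

    @property
    def n_taxa(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def spearman_all_pairs(V: TransformedMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p-values (t approximation).

    Constant columns have undefined rank correlation; their pairs are
    reported as rho = 0, p = 1 with a warning naming the taxa.
    """
    if isinstance(V, TransformedMatrix):
        mat = V.v
        ids = V.taxon_ids
    else:
        mat = np.asarray(V, dtype=float)
        ids = [str(j) for j in range(mat.shape[1])]
    n, p = mat.shape
    if n < 4:
        raise ValueError("need at least 4 samples for Spearman p-values")
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)  # average ranks for ties
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        names = [ids[j] for j in np.flatnonzero(constant)]
        warnings.warn(
            f"constant columns have undefined Spearman correlation: {names}; "
            "their pairs are set to rho=0, p=1",
            stacklevel=2,
        )
    safe = ranks.copy()
    # give constant columns unit variance so corrcoef is finite; overwritten below
    safe[:, constant] = np.arange(n)[:, None]
    rho = np.corrcoef(safe, rowvar=False)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    bad = constant[:, None] | constant[None, :]
    rho[bad] = 0.0
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p_raw = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p_raw = (p_raw + p_raw.T) / 2.0
    p_raw[bad] = 1.0
    np.fill_diagonal(p_raw, 0.0)
    return rho, p_raw


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over the distinct taxon pairs.

    Only the p(p-1)/2 upper-triangle values enter the adjustment (using the
    full symmetric matrix would double-count every test); the adjusted
    values are mirrored back symmetrically.
    """
    P = np.asarray(p_raw, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("p-value matrix must be square")
    if not np.allclose(P, P.T):
        raise ValueError("p-value matrix must be symmetric")
    if np.any((P < 0) | (P > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    iu = np.triu_indices_from(P, k=1)
    flat = P[iu]
    adj = np.empty_like(flat)
    if flat.size:
        adj = multipletests(flat, method="fdr_bh")[1]
    out = np.zeros_like(P)
    out[iu] = adj
    out = out + out.T
    return out


def build_adjacency(
    rho: np.ndarray,
    p_adj: np.ndarray,
    alpha: float = 0.05,
    taxon_ids: list[str] | None = None,
    p_raw: np.ndarray | None = None,
) -> Network:
    """Threshold adjusted p-values into a binary network: edge iff p_adj < alpha.

    alpha = 0 is allowed as a boundary case and yields the empty network.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    P = np.asarray(p_adj, dtype=float)
    A = (P < alpha).astype(np.int8)
    np.fill_diagonal(A, 0)
    A = np.maximum(A, A.T)
    if taxon_ids is None:
        taxon_ids = [str(j) for j in range(A.shape[0])]
    net = Network(A, list(taxon_ids), rho=np.asarray(rho, float), p_raw=p_raw,
                  p_adj=P, alpha=alpha)
    logger.info("network: %d taxa, %d edges at alpha=%g", net.n_taxa, net.n_edges, alpha)
    return net


def build_network(V: TransformedMatrix, alpha: float = 0.05) -> Network:
    """Full first-stage pipeline: Spearman, BH adjustment, thresholding."""
    rho, p_raw = spearman_all_pairs(V)
    p_adj = bh_adjust(p_raw)
    return build_adjacency(rho, p_adj, alpha=alpha, taxon_ids=list(V.taxon_ids), p_raw=p_raw)


def write_network(net: Network, path: str | Path, fmt: str = "matrix") -> None:
    """Write a network as a full 0/1 matrix TSV or an undirected edge list."""
    path = Path(path)
    if fmt == "matrix":
        pd.DataFrame(net.adjacency, index=net.taxon_ids, columns=net.taxon_ids).to_csv(
            path, sep="\t"
        )
    elif fmt == "edgelist":
        iu = np.triu_indices(net.n_taxa, k=1)
        rows = [
            (net.taxon_ids[i], net.taxon_ids[j])
            for i, j in zip(*iu)
            if net.adjacency[i, j]
        ]
        pd.DataFrame(rows, columns=["taxon_a", "taxon_b"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_adjacency(path: str | Path, fmt: str = "matrix",
                   taxon_ids: list[str] | None = None) -> Network:
    """Read a network from a matrix TSV or an edge list.

    Asymmetric matrices are symmetrized by logical OR and self-loops
    dropped, each with a warning.
    """
    path = Path(path)
    if fmt == "matrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"{path}: adjacency matrix is not square {df.shape}")
        A = df.to_numpy(dtype=float)
        if np.any((A != 0) & (A != 1)):
            raise ValueError(f"{path}: adjacency entries must be 0/1")
        A = A.astype(np.int8)
        if not np.array_equal(A, A.T):
            warnings.warn(f"{path}: asymmetric adjacency symmetrized by OR", stacklevel=2)
            A = np.maximum(A, A.T)
        if np.any(np.diag(A) != 0):
            warnings.warn(f"{path}: self-loops dropped", stacklevel=2)
            np.fill_diagonal(A, 0)
        return Network(A, [str(i) for i in df.index])
    if fmt == "edgelist":
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: edge list needs two columns")
        pairs = df.iloc[:, :2].astype(str)
        if taxon_ids is None:
            taxon_ids = sorted(set(pairs.iloc[:, 0]) | set(pairs.iloc[:, 1]))
        index = {t: i for i, t in enumerate(taxon_ids)}
        A = np.zeros((len(taxon_ids), len(taxon_ids)), dtype=np.int8)
        for a, b in pairs.itertuples(index=False):
            if a not in index or b not in index:
                missing = a if a not in index else b
                raise ValueError(f"{path}: unknown taxon {missing!r} in edge list")
            if a == b:
                warnings.warn(f"{path}: self-loop on {a!r} dropped", stacklevel=2)
                continue
            A[index[a], index[b]] = 1
            A[index[b], index[a]] = 1
        return Network(A, list(taxon_ids))
    raise ValueError(f"unknown network format {fmt!r}")


def stats_table(net: Network) -> pd.DataFrame:
    """Long-format per-pair table: taxon_a, taxon_b, rho, p_raw, p_adj, edge."""
    iu = np.triu_indices(net.n_taxa, k=1)
    cols = {
        "taxon_a": [net.taxon_ids[i] for i in iu[0]],
        "taxon_b": [net.taxon_ids[j] for j in iu[1]],
    }
    for name, layer in (("rho", net.rho), ("p_raw", net.p_raw), ("p_adj", net.p_adj)):
        if layer is not None:
            cols[name] = layer[iu]
    cols["edge"] = net.adjacency[iu]
    return pd.DataFrame(cols)
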