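"""Same-parent indicator matrix from one level of the taxonomic tree.

For species-level nodes the natural parent is the genus: ``q[j, j'] = 1``
when taxa j and j' share a parent label, zero otherwise (and on the
diagonal). The matrix is a disjoint union of cliques, one per multi-member
parent. Only a single parent level should be used — incorporating ranks
too far up the tree collapses all taxa into one neighborhood and the prior
becomes useless.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TaxonomyTable:
    """One parent label (e.g. genus) per taxon."""

    taxon_ids: list[str]
    parent_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.taxon_ids) != len(self.parent_labels):
            raise ValueError("taxon_ids and parent_labels must align")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids in taxonomy")
        if any(str(g).strip() == "" for g in self.parent_labels):
            raise ValueError("empty parent label")

    def parent_of(self) -> dict[str, str]:
        return dict(zip(map(str, self.taxon_ids), map(str, self.parent_labels)))


@dataclass
class ParentMatrix:
    """Binary same-parent matrix Q: symmetric, zero diagonal, union of cliques."""

    q: np.ndarray
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        Q = np.asarray(self.q)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        if not np.array_equal(Q, Q.T):
            raise ValueError("Q must be symmetric")
        if np.any(np.diag(Q) != 0):
            raise ValueError("Q must have zero diagonal")
        if np.any((Q != 0) & (Q != 1)):
            raise ValueError("Q must be binary")
        self.q = Q.astype(np.int8)
        if len(self.taxon_ids) != Q.shape[0]:
            raise ValueError("taxon_ids length does not match Q")

    @property
    def n_taxa(self) -> int:
        return self.q.shape[0]


def read_taxonomy(path: str | Path, header: bool = True) -> TaxonomyTable:
    """Read a two-column delimited file (taxon_id, parent_label)."""
    df = pd.read_csv(path, sep=None, engine="python",
                     header=0 if header else None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (taxon_id, parent_label)")
    return TaxonomyTable(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist())


def build_parent_matrix(tax: TaxonomyTable, taxon_order: list[str]) -> ParentMatrix:
    """Build Q with rows/columns in ``taxon_order``.

    Every taxon in ``taxon_order`` must be annotated; use
    :func:`align_to_network` for the forgiving variant.
    """
    if len(set(taxon_order)) != len(taxon_order):
        raise ValueError("duplicate taxa in taxon_order")
    parent = tax.parent_of()
    missing = [t for t in taxon_order if str(t) not in parent]
    if missing:
        raise ValueError(f"taxa missing from taxonomy: {missing}")
    labels = np.array([parent[str(t)] for t in taxon_order])
    Q = (labels[:, None] == labels[None, :]).astype(np.int8)
    np.fill_diagonal(Q, 0)
    groups = pd.Series(labels).value_counts()
    logger.info(
        "parent matrix: %d parent groups, %d singletons",
        groups.size, int((groups == 1).sum()),
    )
    return ParentMatrix(Q, [str(t) for t in taxon_order])


def align_to_network(net, tax: TaxonomyTable) -> ParentMatrix:
    """Build Q in the network's taxon order, tolerating missing annotation.

    Taxa absent from the taxonomy receive a unique singleton parent (their
    Q row is all zero) with a warning, so missing annotation degrades the
    prior to non-informativeness for those taxa instead of failing.
    """
    parent = tax.parent_of()
    labels = []
    missing = []
    for i, t in enumerate(net.taxon_ids):
        if str(t) in parent:
            labels.append(f"P::{parent[str(t)]}")
        else:
            labels.append(f"S::{i}")  # unique singleton parent
            missing.append(str(t))
    if missing:
        warnings.warn(
            f"{len(missing)} network taxa missing from taxonomy get singleton "
            f"parents: {missing}",
            stacklevel=2,
        )
    arr = np.array(labels)
    Q = (arr[:, None] == arr[None, :]).astype(np.int8)
    np.fill_diagonal(Q, 0)
    return ParentMatrix(Q, [str(t) for t in net.taxon_ids])
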