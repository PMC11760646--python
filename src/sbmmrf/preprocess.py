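"""Count loading, prevalence filtering and the modified centered-log-ratio transform.

Taxonomic abundance tables are compositional (each sample carries only
relative information) and zero-inflated. The classical centered-log-ratio
(CLR) transform requires a pseudo-count that disguises zeros; the modified
CLR (MCLR) used here instead transforms only the non-zero part of each
sample,

    v_ij = 0                                    if x_ij = 0
    v_ij = log(x_ij / g(x_i)) + eps_i           if x_ij > 0

where ``g(x_i)`` is the geometric mean of the *non-zero* relative
abundances of sample ``i``. With ``eps_i = 0`` this is the robust CLR;
with ``eps_i = 1 + |min_j log(x_ij / g(x_i))|`` every transformed non-zero
is strictly positive, so the value 0 remains reserved for absent taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Orientation = Literal["samples-rows", "taxa-rows"]
ShiftMode = Literal["shifted", "robust_clr"]


def _check_ids(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes}")
    if any(str(x).strip() == "" for x in ids):
        raise ValueError(f"empty {what} identifier")


@dataclass
class AbundanceMatrix:
    """Raw counts, samples in rows, taxa in columns.

    Counts are validated as non-negative (and integral unless
    ``allow_noninteger``) but stored as floats so pre-normalized tables can
    flow through the same pipeline.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    allow_noninteger: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n, p = self.counts.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        _check_ids(list(map(str, self.taxon_ids)), "taxon")
        _check_ids(list(map(str, self.sample_ids)), "sample")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative values")
        if not self.allow_noninteger and not np.allclose(
            self.counts, np.round(self.counts)
        ):
            raise ValueError(
                "counts contain non-integral values; pass allow_noninteger=True "
                "for pre-normalized abundance tables"
            )
        empty = np.flatnonzero(self.counts.sum(axis=1) == 0)
        if empty.size:
            names = [self.sample_ids[i] for i in empty]
            raise ValueError(f"samples with all-zero counts: {names}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class CompositionMatrix:
    """Relative abundances; every row lies on the simplex."""

    rel: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.rel = np.asarray(self.rel, dtype=float)
        sums = self.rel.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")
        if np.any(self.rel < 0):
            raise ValueError("negative relative abundance")


@dataclass
class TransformedMatrix:
    """MCLR-transformed values; zeros are exact zeros."""

    v: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    shift_mode: ShiftMode = "shifted"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.v, index=self.sample_ids, columns=self.taxon_ids)


def read_counts(
    path: str | Path,
    orientation: Orientation = "samples-rows",
    allow_noninteger: bool = False,
) -> AbundanceMatrix:
    """Read a delimited count table into samples x taxa orientation.

    The first column holds row identifiers and the header row holds column
    identifiers. Tab and comma delimiters are auto-detected.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    # pandas silently renames duplicate header fields, so check them raw
    header = path.open().readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    fields = [f for f in header.split(sep)[1:] if f.strip()]
    if len(set(fields)) != len(fields):
        raise ValueError(f"{path}: duplicate identifiers in header row")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in count table ({exc})") from exc
    if orientation == "taxa-rows":
        values = values.T
        sample_ids = [str(c) for c in df.columns]
        taxon_ids = [str(i) for i in df.index]
    elif orientation == "samples-rows":
        sample_ids = [str(i) for i in df.index]
        taxon_ids = [str(c) for c in df.columns]
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = AbundanceMatrix(values, taxon_ids, sample_ids, allow_noninteger=allow_noninteger)
    logger.info("read %d samples x %d taxa from %s", mat.n_samples, mat.n_taxa, path)
    return mat


def filter_taxa(Y: AbundanceMatrix, min_nonzero: int = 1) -> AbundanceMatrix:
    """Keep taxa observed (count > 0) in at least ``min_nonzero`` samples.

    Column order is preserved. Typical practice for species-level shotgun
    data is to drop very rare taxa (e.g. present in fewer than seven
    samples) before network estimation; the threshold is dataset-specific.
    """
    if min_nonzero < 1:
        raise ValueError("min_nonzero must be >= 1")
    prevalence = (Y.counts > 0).sum(axis=0)
    keep = prevalence >= min_nonzero
    if not keep.any():
        raise ValueError("filter removed every taxon")
    removed = [t for t, k in zip(Y.taxon_ids, keep) if not k]
    if removed:
        logger.info("filter_taxa removed %d taxa: %s", len(removed), removed)
    return AbundanceMatrix(
        Y.counts[:, keep],
        [t for t, k in zip(Y.taxon_ids, keep) if k],
        list(Y.sample_ids),
        allow_noninteger=True,
    )


def to_relative(Y: AbundanceMatrix) -> CompositionMatrix:
    """Row-normalize counts to relative abundances, preserving the zero pattern."""
    sums = Y.counts.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        names = [Y.sample_ids[i] for i in zero]
        raise ValueError(f"zero row sum for samples {names}")
    return CompositionMatrix(Y.counts / sums[:, None], list(Y.taxon_ids), list(Y.sample_ids))


def mclr_transform(X: CompositionMatrix, shift_mode: ShiftMode = "shifted") -> TransformedMatrix:
    """Apply the modified centered-log-ratio transform row by row.

    ``robust_clr`` sets the per-sample shift to zero (non-zero values in
    each row are centered, summing to zero); ``shifted`` adds
    ``1 + |min log-ratio|`` per row so non-zero output is strictly positive.
    The geometric mean of the non-zeros is computed in log space.
    """
    rel = X.rel
    nz = rel > 0
    if np.any(~nz.any(axis=1)):
        raise ValueError("row with all zeros cannot be transformed")
    with np.errstate(divide="ignore"):
        logs = np.where(nz, np.log(rel, where=nz, out=np.zeros_like(rel)), 0.0)
    log_gmean = logs.sum(axis=1) / nz.sum(axis=1)
    raw = np.where(nz, logs - log_gmean[:, None], 0.0)
    if shift_mode == "robust_clr":
        v = raw
    elif shift_mode == "shifted":
        row_min = np.where(nz, raw, np.inf).min(axis=1)
        eps = 1.0 + np.abs(row_min)
        v = np.where(nz, raw + eps[:, None], 0.0)
    else:
        raise ValueError(f"unknown shift_mode {shift_mode!r}")
    return TransformedMatrix(v, list(X.taxon_ids), list(X.sample_ids), shift_mode=shift_mode)


def write_transformed(V: TransformedMatrix, path: str | Path) -> None:
    """Write the transformed matrix as TSV with full-precision floats."""
    V.to_frame().to_csv(path, sep="\t", float_format=None)
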