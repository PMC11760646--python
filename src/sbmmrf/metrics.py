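"""Adjusted Rand index from pair counts, plus the simulation evaluation harness.

For two labelings of the same ``p`` items, classify every unordered pair as

    a — same cluster in both,        b — same in the first only,
    c — same in the second only,     d — different in both,

with ``a + b + c + d = C(p, 2)``. The adjusted Rand index is

    ARI = [ C(p,2) (a + d) - T ] / [ C(p,2)^2 - T ],
    T = (a+b)(a+c) + (c+d)(b+d)

which is 1 for identical partitions, has expectation ~0 for independent
random labelings, and can be negative (never below -1) for agreement worse
than chance. ARI is symmetric and invariant to relabeling either argument,
which makes it the standard validation metric for clustering methods whose
label identities are arbitrary (label switching).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from ._util import derived_seed as _derived_seed
from .sbm import GibbsConfig, MRFPrior, run_gibbs


@dataclass
class PairCounts:
    """Unordered-pair agreement counts between two labelings."""

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _check_pair(z1, z2) -> tuple[np.ndarray, np.ndarray]:
    z1 = np.asarray(z1).ravel()
    z2 = np.asarray(z2).ravel()
    if z1.shape != z2.shape:
        raise ValueError(f"label vectors differ in length: {z1.size} vs {z2.size}")
    if z1.size < 2:
        raise ValueError("need at least two items")
    return z1, z2


def pair_counts(z1, z2) -> PairCounts:
    """Count pair agreements via the contingency table (O(p + K1*K2))."""
    z1, z2 = _check_pair(z1, z2)
    p = z1.size
    _, i1 = np.unique(z1, return_inverse=True)
    _, i2 = np.unique(z2, return_inverse=True)
    C = np.zeros((i1.max() + 1, i2.max() + 1), dtype=np.int64)
    np.add.at(C, (i1, i2), 1)
    a = int((C * (C - 1) // 2).sum())
    r = C.sum(axis=1)
    s = C.sum(axis=0)
    same1 = int((r * (r - 1) // 2).sum())
    same2 = int((s * (s - 1) // 2).sum())
    total = p * (p - 1) // 2
    b = same1 - a
    c = same2 - a
    d = total - a - b - c
    return PairCounts(a, b, c, d)


def ari(z1, z2) -> float:
    """Adjusted Rand index of two labelings, from pair counts.

    A zero denominator only occurs when both partitions are the same
    trivial partition (all-singletons or one block), where 1.0 is returned
    by convention.
    """
    pc = pair_counts(z1, z2)
    a, b, c, d = pc.a, pc.b, pc.c, pc.d
    n2 = pc.total
    t = (a + b) * (a + c) + (c + d) * (b + d)
    den = n2 * n2 - t
    if den == 0:
        return 1.0
    return (n2 * (a + d) - t) / den


def enumerate_partitions(n_items: int, max_blocks: int) -> list[np.ndarray]:
    """All set partitions of ``n_items`` into at most ``max_blocks`` blocks.

    Partitions are returned as canonical label vectors (restricted growth
    strings: the first item has label 0 and each new label is the smallest
    unused one), so each partition appears exactly once. Useful for
    exhaustive small-instance checks of partition statistics.
    """
    out: list[np.ndarray] = []

    def extend(prefix: list[int], used: int) -> None:
        if len(prefix) == n_items:
            out.append(np.array(prefix))
            return
        for lab in range(min(used + 1, max_blocks)):
            extend(prefix + [lab], max(used, lab + 1))

    extend([], 0)
    return out


def _fit_map(G, Q, K: int, d: float, seed: int, config: GibbsConfig) -> np.ndarray:
    from .inference import map_estimate  # local import avoids a cycle

    cfg = GibbsConfig(n_iter=config.n_iter, burn_in=config.burn_in,
                      a_omega=config.a_omega, b_omega=config.b_omega,
                      seed=seed, relabel=config.relabel)
    chain = run_gibbs(G, Q, K, prior=MRFPrior(d=d), config=cfg)
    return map_estimate(chain)[0]


def sensitivity_study(datasets: Sequence, d_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
                      config: GibbsConfig | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Refit every simulated dataset at each MRF coupling d and score by ARI.

    For each dataset (carrying its true labels) and each d, the model is
    fit with a seed derived from the dataset's replicate and d index, and
    ARI(truth, MAP labels) recorded. Paired Wilcoxon signed-rank tests
    compare d = 0 against every d > 0 within each (K, strength) setting.
    Returns the long-format record table and the Wilcoxon summary.
    """
    config = config if config is not None else GibbsConfig(n_iter=400)
    records = []
    for ds in datasets:
        K = int(ds.z_true.max()) + 1
        for di, d in enumerate(d_grid):
            seed = _derived_seed(ds.seed, di)
            z_hat = _fit_map(ds.G, ds.Q, K, float(d), seed, config)
            records.append({
                "K": K,
                "strength": ds.strength,
                "method": f"sbm-mrf(d={d:g})",
                "d": float(d),
                "replicate": ds.replicate_id,
                "ari": ari(ds.z_true, z_hat),
            })
    table = pd.DataFrame(records)

    tests = []
    base = table[table["d"] == 0.0]
    for (K, strength), grp in table.groupby(["K", "strength"]):
        ref = base[(base["K"] == K) & (base["strength"] == strength)]
        ref = ref.set_index("replicate")["ari"]
        for d in sorted({v for v in d_grid if v > 0}):
            alt = grp[grp["d"] == d].set_index("replicate")["ari"]
            common = ref.index.intersection(alt.index)
            x = ref.loc[common].to_numpy()
            y = alt.loc[common].to_numpy()
            if np.allclose(x, y):
                stat, pval = np.nan, 1.0
            else:
                stat, pval = wilcoxon(x, y)
            tests.append({"K": K, "strength": strength, "d": d,
                          "n_pairs": len(common), "statistic": stat,
                          "p_value": float(pval),
                          "mean_ari_d0": float(x.mean()),
                          "mean_ari_d": float(y.mean())})
    return table, pd.DataFrame(tests)


def compare_external_labels(truth: Mapping[str, pd.Series],
                            method_labels: Mapping[str, Mapping[str, "pd.Series | str | Path"]],
                            ) -> pd.DataFrame:
    """Score externally produced partitions against simulation truth.

    ``truth`` maps replicate id to a Series of true labels indexed by taxon
    id; ``method_labels`` maps method name to replicate id to either a
    Series or a path to a two-column file (taxon_id, label). Labels are
    aligned by taxon id; unknown taxa or missing replicates fail loudly.
    """
    records = []
    for method, reps in method_labels.items():
        for rep, labels in reps.items():
            if rep not in truth:
                raise ValueError(f"method {method!r}: unknown replicate {rep!r}")
            ref = truth[rep]
            if isinstance(labels, (str, Path)):
                df = pd.read_csv(labels, sep=None, engine="python", dtype=str)
                labels = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0])
            unknown = labels.index.difference(ref.index)
            if len(unknown):
                raise ValueError(
                    f"method {method!r} replicate {rep!r}: unknown taxa {list(unknown)}"
                )
            missing = ref.index.difference(labels.index)
            if len(missing):
                raise ValueError(
                    f"method {method!r} replicate {rep!r}: missing taxa {list(missing)}"
                )
            aligned = labels.loc[ref.index]
            records.append({"method": method, "replicate": rep,
                            "ari": ari(ref.to_numpy(), aligned.to_numpy())})
    return pd.DataFrame(records)
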