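"""Leave-one-out validation and granularity sweeps.

When no trustworthy ground truth exists, a consensus of the *other*
methods serves as a pseudo-ground-truth against which each base clustering
is scored (leave-one-out ARI).  Orthogonally, sweeping the mean
cross-method entropy over a grid of (number of clusters k) × (number of
smoothest base clusterings n) exposes the granularity at which methods
agree best: the k with the lowest mean CME is the cluster count the method
ensemble supports most strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import kmodes_consensus, lca_consensus, weighted_consensus
from .labelings import LabelingCollection
from .metrics import _ari, cross_method_entropy
from .selection import select_smoothest

__all__ = ["SweepGrid", "leave_one_out", "sweep_grid", "run_consensus"]


def run_consensus(
    collection: LabelingCollection,
    algorithm: str,
    k: int | None,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Dispatch to one of the consensus algorithms; returns labels."""
    if algorithm == "kmodes":
        if k is None:
            raise ValueError("kmodes requires a cluster count")
        return kmodes_consensus(collection, k, seed=seed, **kwargs).labels
    if algorithm == "lca":
        if k is None:
            raise ValueError("lca requires a cluster count")
        return lca_consensus(collection, k, seed=seed, **kwargs)[0].labels
    if algorithm == "weighted":
        return weighted_consensus(collection, k=k, seed=seed, **kwargs).labels
    raise ValueError(f"unknown consensus algorithm {algorithm!r}")


def leave_one_out(
    collection: LabelingCollection,
    se_values,
    k: int,
    algorithm: str = "lca",
    n_base: int = 6,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """ARI of each base clustering against its leave-one-out consensus.

    For every column c, a consensus is built from the ``n_base`` smoothest
    of the remaining columns (one per algorithm), excluding c itself, and
    ``ARI(c, consensus)`` is returned.  High values mean the method agrees
    with the ensemble of its peers.
    """
    se_values = np.asarray(se_values, dtype=float)
    m = collection.n_labelings
    if se_values.shape != (m,):
        raise ValueError("need exactly one SE value per column")
    if m < n_base + 1:
        raise ValueError(
            f"leave-one-out with n_base={n_base} needs at least {n_base + 1} "
            f"columns, got {m}"
        )
    out = np.empty(m)
    for c in range(m):
        others = [j for j in range(m) if j != c]
        rest = collection.subset_columns(others)
        selected, _ = select_smoothest(
            rest, se_values[others], n=n_base, dedupe_by_algorithm=True
        )
        labels = run_consensus(selected, algorithm, k, seed=seed, **kwargs)
        out[c] = _ari(collection.column(c), labels)
    return out


@dataclass
class SweepGrid:
    """Mean CME over a (cluster count k) × (n smoothest methods) grid.

    ``mean_cme[i, j]`` is the mean cross-method entropy of the
    ``n_values[j]`` smoothest deduplicated base clusterings at
    ``k_values[i]`` clusters; NaN where a cell is infeasible.  ``status``
    holds 'ok', 'degenerate-n1' (a single labeling cannot disagree with
    itself; the cell is 0 by definition), or an infeasibility reason.
    """

    k_values: list[int]
    n_values: list[int]
    mean_cme: np.ndarray
    status: np.ndarray
    algorithm: str
    seed: int
    consensus_labels: dict = field(default_factory=dict)

    def argmin_k(self, n: int) -> int:
        """k with the lowest mean CME in the column for *n* methods."""
        j = self.n_values.index(n)
        col = self.mean_cme[:, j]
        if np.isnan(col).all():
            raise ValueError(f"no feasible cell at n={n}")
        return self.k_values[int(np.nanargmin(col))]


def sweep_grid(
    collections_by_k: dict[int, LabelingCollection],
    se_values_by_k: dict[int, np.ndarray],
    n_values,
    algorithm: str = "lca",
    seed: int = 0,
    compute_consensus: bool = False,
) -> SweepGrid:
    """Mean-CME grid over cluster counts × number of smoothest methods.

    Each collection in ``collections_by_k`` must hold only base clusterings
    with exactly k classes; cells with fewer than n available deduplicated
    columns are marked infeasible rather than raising.
    """
    k_values = sorted(collections_by_k)
    n_values = list(n_values)
    grid = np.full((len(k_values), len(n_values)), np.nan)
    status = np.full((len(k_values), len(n_values)), "", dtype=object)
    consensus_labels: dict = {}
    for i, k in enumerate(k_values):
        coll = collections_by_k[k]
        se = np.asarray(se_values_by_k[k], dtype=float)
        for j, n in enumerate(n_values):
            if n < 1:
                status[i, j] = "infeasible: n must be >= 1"
                continue
            if coll.n_labelings < n:
                status[i, j] = (
                    f"infeasible: {coll.n_labelings} columns available, {n} requested"
                )
                continue
            with np.errstate(all="ignore"):
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    selected, _ = select_smoothest(
                        coll, se, n=n, dedupe_by_algorithm=True
                    )
            if selected.n_labelings < n:
                status[i, j] = (
                    f"infeasible: only {selected.n_labelings} columns survive "
                    f"deduplication, {n} requested"
                )
                continue
            if n == 1:
                grid[i, j] = 0.0
                status[i, j] = "degenerate-n1"
            else:
                grid[i, j] = cross_method_entropy(selected).mean()
                status[i, j] = "ok"
            if compute_consensus and n >= 2:
                consensus_labels[(k, n)] = run_consensus(
                    selected, algorithm, k, seed=seed
                )
    return SweepGrid(
        k_values=k_values,
        n_values=n_values,
        mean_cme=grid,
        status=status,
        algorithm=algorithm,
        seed=seed,
        consensus_labels=consensus_labels,
    )
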