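"""Base-clustering selection rules.

Before building a consensus, the pool of base clusterings is narrowed:
degenerate labelings dominated by one giant cluster are filtered out, a
concordant block of mutually agreeing methods is identified on the pairwise
agreement matrix, and within that block the spatially smoothest clusterings
are ranked — keeping at most one clustering per algorithm so that a method
run with many configurations cannot dominate the consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .labelings import LabelingCollection
from .metrics import AgreementMatrix

__all__ = [
    "SelectionReport",
    "filter_imbalanced",
    "select_smoothest",
    "concordance_block",
]

DEFAULT_IMBALANCE_THRESHOLD = 0.9
DEFAULT_MIN_BLOCK_SIZE = 3


@dataclass
class SelectionReport:
    """Which columns a selection step kept, and why the rest were removed.

    ``removed`` pairs each dropped column's provenance with a reason in
    {imbalance, duplicate-algorithm, out-of-block, rank-cutoff}.
    """

    kept: list[tuple[str, str]]
    removed: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    block_assignments: list[int] | None = None
    n_groups: int | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kept": [list(p) for p in self.kept],
            "removed": [[list(p), reason] for p, reason in self.removed],
            "block_assignments": self.block_assignments,
            "n_groups": self.n_groups,
            "notes": self.notes,
        }


def filter_imbalanced(
    collection: LabelingCollection,
    threshold: float = DEFAULT_IMBALANCE_THRESHOLD,
) -> tuple[LabelingCollection, SelectionReport]:
    """Drop columns whose modal class holds strictly more than *threshold*
    of the observations (default 0.9: one cluster covering >90% of cells)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = collection.n_obs
    keep_idx, removed = [], []
    for m in range(collection.n_labelings):
        _, counts = np.unique(collection.column(m), return_counts=True)
        if counts.max() / n > threshold:
            removed.append((collection.provenance[m], "imbalance"))
        else:
            keep_idx.append(m)
    if not keep_idx:
        raise ValueError(
            f"every labeling failed the class-imbalance filter at threshold "
            f"{threshold}; consider a higher threshold"
        )
    report = SelectionReport(
        kept=[collection.provenance[m] for m in keep_idx], removed=removed
    )
    return collection.subset_columns(keep_idx), report


def select_smoothest(
    collection: LabelingCollection,
    se_values,
    n: int,
    dedupe_by_algorithm: bool = True,
) -> tuple[LabelingCollection, SelectionReport]:
    """Keep the *n* smoothest (lowest-SE) base clusterings.

    With ``dedupe_by_algorithm`` (the default), only the smoothest
    clustering of each method survives first, enforcing algorithm diversity
    when a method was run under several configurations.  Ties are broken by
    (method_id, config_id) lexicographic order.  If fewer than *n* columns
    survive deduplication, all survivors are kept with a warning.
    """
    se_values = np.asarray(se_values, dtype=float)
    if se_values.shape != (collection.n_labelings,):
        raise ValueError("need exactly one SE value per column")
    if n < 1:
        raise ValueError("n must be >= 1")

    removed: list[tuple[tuple[str, str], str]] = []
    notes: list[str] = []
    order_key = lambda m: (se_values[m], collection.provenance[m])  # noqa: E731
    candidates = sorted(range(collection.n_labelings), key=order_key)

    if dedupe_by_algorithm:
        survivors, seen = [], set()
        for m in candidates:
            method = collection.provenance[m][0]
            if method in seen:
                removed.append((collection.provenance[m], "duplicate-algorithm"))
            else:
                seen.add(method)
                survivors.append(m)
    else:
        survivors = candidates

    if n > len(survivors):
        notes.append(
            f"requested n={n} but only {len(survivors)} column(s) survive "
            "deduplication; keeping all"
        )
        warnings.warn(notes[-1], stacklevel=2)
        kept_idx = survivors
    else:
        kept_idx = survivors[:n]
        for m in survivors[n:]:
            removed.append((collection.provenance[m], "rank-cutoff"))

    kept_idx = sorted(kept_idx)  # preserve original column order
    report = SelectionReport(
        kept=[collection.provenance[m] for m in kept_idx],
        removed=removed,
        notes=notes,
    )
    return collection.subset_columns(kept_idx), report


def concordance_block(
    agreement: AgreementMatrix,
    n_groups: int = 2,
    min_block_size: int = DEFAULT_MIN_BLOCK_SIZE,
) -> SelectionReport:
    """Identify the concordant block of methods on the agreement matrix.

    Rows of the pairwise-ARI matrix are hierarchically clustered (Euclidean
    row distance, complete linkage) and the tree is cut into *n_groups*.
    The selected block is the group with the highest mean within-group
    agreement (off-diagonal entries) among groups of size >=
    *min_block_size*.
    """
    a = np.asarray(agreement.values, dtype=float)
    m = a.shape[0]
    if m < n_groups:
        raise ValueError(f"cannot cut {m} columns into {n_groups} groups")
    groups = fcluster(linkage(pdist(a), method="complete"), t=n_groups, criterion="maxclust")

    best_gid, best_score = None, -np.inf
    sizes = {}
    for gid in np.unique(groups):
        members = np.flatnonzero(groups == gid)
        sizes[int(gid)] = len(members)
        if len(members) < min_block_size:
            continue
        sub = a[np.ix_(members, members)]
        score = float(sub[~np.eye(len(members), dtype=bool)].mean())
        # tie-break: earliest first member, for determinism
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12
            and best_gid is not None
            and members[0] < np.flatnonzero(groups == best_gid)[0]
        ):
            best_gid, best_score = int(gid), score
    if best_gid is None:
        raise ValueError(
            f"no group reaches min_block_size={min_block_size}; group sizes: {sizes}"
        )

    kept, removed = [], []
    for i in range(m):
        if groups[i] == best_gid:
            kept.append(agreement.provenance[i])
        else:
            removed.append((agreement.provenance[i], "out-of-block"))
    return SelectionReport(
        kept=kept,
        removed=removed,
        block_assignments=[int(g) for g in groups],
        n_groups=n_groups,
        notes=[f"selected block mean agreement {best_score:.4f}"],
    )
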