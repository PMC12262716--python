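"""Entropy-based spatial metrics and partition-agreement machinery.

Two entropy diagnostics sit at the center of the consensus workflow:

* **Smoothness entropy (SE)** scores the spatial coherence of a single
  labeling: for every observation, the Shannon entropy of the labels in its
  k-nearest-neighbor neighborhood (itself included) is computed, and SE is
  the mean over observations.  Lower SE means spatially smoother domains —
  fewer boundaries between labels.
* **Cross-method entropy (CME)** scores disagreement *across* labelings:
  cluster codes of the different labelings are first matched to a common
  reference with the Hungarian method on the confusion matrix, then the
  per-observation Shannon entropy across the aligned labels is computed.
  Because the choice of reference is arbitrary, the entropy is averaged over
  every choice of reference labeling.

All entropies use the natural logarithm (values in nats).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.special import xlogy
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .labelings import LabelingCollection, SpatialLabeling

__all__ = [
    "NeighborGraph",
    "EntropyField",
    "AgreementMatrix",
    "shannon_entropy",
    "build_knn_graph",
    "smoothness_entropy",
    "border_mask",
    "pairwise_agreement",
    "align_labelings",
    "cross_method_entropy",
]

#: neighborhood size used for smoothness entropy
DEFAULT_SE_K = 6
#: neighborhood size and distance cutoff used for border-spot detection
DEFAULT_BORDER_K = 4
DEFAULT_BORDER_MAX_DISTANCE = 1.5


def shannon_entropy(labels) -> float:
    """Shannon entropy of the empirical class frequencies, in nats.

    ``H(X) = -sum_i p_i log p_i`` with ``p_i = n_i / n`` the empirical
    probability of class *i*; ``0 log 0`` is taken as 0.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot compute entropy of an empty vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-np.sum(xlogy(p, p)))


def _row_entropies(mat: np.ndarray) -> np.ndarray:
    """Shannon entropy of each row of an integer matrix, vectorized."""
    n, m = mat.shape
    s = np.sort(mat, axis=1)
    new_run = np.ones((n, m), dtype=bool)
    new_run[:, 1:] = s[:, 1:] != s[:, :-1]
    starts = np.flatnonzero(new_run.ravel())
    lengths = np.diff(np.append(starts, s.size))
    p = lengths / m
    out = np.zeros(n)
    np.add.at(out, starts // m, -xlogy(p, p))
    return out


@dataclass
class NeighborGraph:
    """k-nearest-neighbor lists with distances, on spatial coordinates.

    Per observation *i*, ``neighbor_indices[i]`` holds the positions of its
    retained neighbors (never *i* itself) with matching
    ``neighbor_distances[i]`` sorted ascending.  If ``max_distance`` is set,
    neighbors farther than the cutoff were removed after the k-selection, so
    an observation may retain fewer than *k* neighbors (possibly none).
    """

    k: int
    neighbor_indices: list[np.ndarray]
    neighbor_distances: list[np.ndarray]
    observation_ids: np.ndarray | None
    max_distance: float | None = None

    @property
    def n_obs(self) -> int:
        return len(self.neighbor_indices)


@dataclass
class EntropyField:
    """Per-observation non-negative entropy values (nats)."""

    values: np.ndarray
    alphabet_bound: float
    observation_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class AgreementMatrix:
    """Symmetric M×M pairwise agreement (ARI or NMI) between labelings."""

    values: np.ndarray
    metric_name: str
    provenance: list[tuple[str, str]]

    @property
    def n_labelings(self) -> int:
        return self.values.shape[0]


def build_knn_graph(
    coords: np.ndarray,
    k: int,
    max_distance: float | None = None,
    observation_ids: np.ndarray | None = None,
) -> NeighborGraph:
    """Euclidean k-nearest-neighbor graph with a deterministic tie-break.

    Equidistant candidates are ordered by observation position (row index),
    so the graph is identical across runs.  ``max_distance`` prunes
    neighbors *after* the k-selection.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of observations ({n})")

    neighbor_indices: list[np.ndarray] = []
    neighbor_distances: list[np.ndarray] = []
    col_idx = np.arange(n)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(coords[start:stop], coords)
        d[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.lexsort((np.broadcast_to(col_idx, d.shape), d))[:, :k]
        dist = np.take_along_axis(d, order, axis=1)
        for r in range(stop - start):
            idx, dd = order[r], dist[r]
            if max_distance is not None:
                keep = dd <= max_distance
                idx, dd = idx[keep], dd[keep]
            neighbor_indices.append(idx.copy())
            neighbor_distances.append(dd.copy())
    return NeighborGraph(
        k=k,
        neighbor_indices=neighbor_indices,
        neighbor_distances=neighbor_distances,
        observation_ids=None if observation_ids is None
        else np.asarray(observation_ids, dtype=object),
        max_distance=max_distance,
    )


def _check_graph(labeling: SpatialLabeling, graph: NeighborGraph) -> None:
    if graph.n_obs != labeling.n_obs:
        raise ValueError("neighbor graph and labeling index different observations")
    if graph.observation_ids is not None and not np.array_equal(
        graph.observation_ids.astype(str), labeling.observation_ids.astype(str)
    ):
        raise ValueError("neighbor graph and labeling index different observations")


def smoothness_entropy(
    labeling: SpatialLabeling,
    graph: NeighborGraph | None = None,
    k: int = DEFAULT_SE_K,
) -> tuple[EntropyField, float]:
    """Smoothness entropy of a labeling on its spatial k-NN graph.

    Per observation, the Shannon entropy of the label multiset {own label}
    ∪ {labels of retained neighbors}; the scalar SE is the mean over
    observations.  An observation whose neighbor list is empty (all pruned
    by a distance cutoff) contributes entropy 0.

    If *graph* is None a k-NN graph with ``k`` neighbors (default 6) and no
    distance cutoff is built from the labeling's coordinates.
    """
    if graph is None:
        graph = build_knn_graph(
            labeling.coords, k=k, observation_ids=labeling.observation_ids
        )
    _check_graph(labeling, graph)
    labels = labeling.labels
    values = np.zeros(labeling.n_obs)
    for i, idx in enumerate(graph.neighbor_indices):
        hood = np.concatenate(([labels[i]], labels[idx]))
        values[i] = shannon_entropy(hood)
    bound = float(np.log(max(labeling.n_clusters, 1))) if labeling.n_clusters > 1 else 0.0
    fld = EntropyField(values=values, alphabet_bound=bound, observation_ids=labeling.observation_ids)
    return fld, fld.mean()


def border_mask(
    labeling: SpatialLabeling,
    graph: NeighborGraph | None = None,
    k: int = DEFAULT_BORDER_K,
    max_distance: float | None = DEFAULT_BORDER_MAX_DISTANCE,
) -> np.ndarray:
    """Boolean mask: True where any retained spatial neighbor carries a
    different label.  Defaults k=4 with distance cutoff 1.5; an observation
    with no retained neighbors is not a border spot."""
    if graph is None:
        graph = build_knn_graph(
            labeling.coords,
            k=k,
            max_distance=max_distance,
            observation_ids=labeling.observation_ids,
        )
    _check_graph(labeling, graph)
    labels = labeling.labels
    out = np.zeros(labeling.n_obs, dtype=bool)
    for i, idx in enumerate(graph.neighbor_indices):
        out[i] = bool(idx.size) and bool((labels[idx] != labels[i]).any())
    return out


def _is_single_class(x: np.ndarray) -> bool:
    return len(np.unique(x)) == 1


def _ari(a: np.ndarray, b: np.ndarray) -> float:
    # degenerate partitions (expected index == max index): 1 iff the two are
    # identical as set partitions, else 0
    if _is_single_class(a) or _is_single_class(b):
        same = _is_single_class(a) and _is_single_class(b)
        return 1.0 if same else 0.0
    return float(adjusted_rand_score(a, b))


def pairwise_agreement(
    collection: LabelingCollection, metric: str = "ARI"
) -> AgreementMatrix:
    """Symmetric matrix of pairwise ARI (or NMI) between all base clusterings."""
    if collection.n_labelings < 2:
        raise ValueError("need at least 2 labelings for pairwise agreement")
    metric = metric.upper()
    if metric == "ARI":
        score = _ari
    elif metric == "NMI":
        score = lambda a, b: float(normalized_mutual_info_score(a, b))  # noqa: E731
    else:
        raise ValueError(f"unknown agreement metric {metric!r}")
    m = collection.n_labelings
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = score(collection.column(i), collection.column(j))
    return AgreementMatrix(values=out, metric_name=metric, provenance=list(collection.provenance))


def align_labelings(reference: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Remap each column of *others* onto the reference's cluster codes.

    The optimal code matching maximizes total overlap with the reference
    (assignment-problem optimum on the confusion matrix, Hungarian method).
    When a column has more clusters than the reference, surplus classes keep
    fresh codes beyond the reference alphabet.

    Parameters
    ----------
    reference : (N,) int array of dense cluster codes
    others : (N, J) int array, one column per labeling to align

    Returns
    -------
    (N, J) int array of aligned codes.
    """
    reference = np.asarray(reference)
    others = np.asarray(others)
    if others.ndim == 1:
        others = others[:, None]
    if others.shape[0] != reference.shape[0]:
        raise ValueError("reference and others must share the observation index")
    k_ref = int(reference.max()) + 1
    aligned = np.empty_like(others)
    for j in range(others.shape[1]):
        col = others[:, j]
        k_col = int(col.max()) + 1
        size = max(k_ref, k_col)
        conf = np.zeros((size, size))
        np.add.at(conf, (reference, col), 1.0)
        rows, cols = linear_sum_assignment(-conf)
        mapping = np.empty(size, dtype=np.int64)
        fresh = k_ref
        for r, c in sorted(zip(rows, cols), key=lambda rc: rc[1]):
            if r < k_ref:
                mapping[c] = r
            else:  # matched to a dummy reference class: fresh code
                mapping[c] = fresh
                fresh += 1
        aligned[:, j] = mapping[col]
    return aligned


def cross_method_entropy(
    collection: LabelingCollection, normalized: bool = False
) -> EntropyField:
    """Cross-method entropy: per-observation disagreement across labelings.

    For each choice of reference column *r*, every column is Hungarian-
    aligned to *r* and the per-observation Shannon entropy across the M
    aligned labels is computed; the final CME is the mean of these fields
    over all M reference choices.  Reported in nats; with
    ``normalized=True`` values are divided by the log of the largest aligned
    alphabet.
    """
    m = collection.n_labelings
    if m < 2:
        raise ValueError("cross-method entropy needs at least 2 labelings")
    mat = collection.label_matrix
    total = np.zeros(collection.n_obs)
    max_alpha = 2
    for r in range(m):
        aligned = np.empty_like(mat)
        aligned[:, r] = mat[:, r]
        other_cols = [j for j in range(m) if j != r]
        aligned[:, other_cols] = align_labelings(mat[:, r], mat[:, other_cols])
        max_alpha = max(max_alpha, int(aligned.max()) + 1)
        total += _row_entropies(aligned)
    values = total / m
    bound = float(np.log(min(m, max_alpha)))
    if normalized:
        values = values / np.log(max_alpha)
        bound = 1.0
    return EntropyField(
        values=values, alphabet_bound=bound, observation_ids=collection.observation_ids
    )
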