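"""Synthetic spatial tissues and noisy base clusterings.

Emulates the label outputs of spatially aware clustering methods on a 2-D
tissue with contiguous spatial domains, so the whole consensus/entropy
workflow can be exercised with a known ground truth.  A tissue is a square
lattice with unit spacing whose observations carry domain labels laid out
either as horizontal layers (cortex-like bands) or as a rectangular block
tiling.  Noisy base clusterings are derived from the ground truth by, in
order: optional domain merges/splits (granularity mismatch between
methods), boundary jitter (methods disagreeing about where domain borders
run), iid label flips (salt-and-pepper noise), and an optional label
permutation (cluster codes are arbitrary per method).

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .labelings import LabelingCollection, SpatialLabeling, build_collection

__all__ = [
    "SyntheticTissue",
    "NoiseSpec",
    "generate_tissue",
    "perturb_labeling",
    "generate_collection",
    "default_noise_specs",
    "granularity_specs",
]

# defaults for the study conditions emulated throughout the test-bench:
# moderate salt-and-pepper noise plus disagreement concentrated at borders
DEFAULT_FLIP_RATE = 0.1
DEFAULT_JITTER_PROB = 0.3
DEFAULT_JITTER_RADIUS = 1.0


@dataclass
class SyntheticTissue:
    """A lattice tissue with known, spatially connected domains."""

    coords: np.ndarray
    gt_labels: np.ndarray
    observation_ids: np.ndarray
    layout: str
    n_rows: int
    n_cols: int
    n_domains: int
    seed: int

    @property
    def n_obs(self) -> int:
        return len(self.gt_labels)

    def ground_truth(self) -> SpatialLabeling:
        """The ground-truth domain assignment as a labeling."""
        return SpatialLabeling(
            observation_ids=self.observation_ids,
            coords=self.coords,
            labels=self.gt_labels,
            method_id="ground_truth",
            config_id=self.layout,
            sample_id=f"synthetic_{self.seed}",
        )


@dataclass
class NoiseSpec:
    """How one noisy base clustering is derived from the ground truth.

    flip_rate : per-observation probability of reassignment to a uniformly
        random *other* label.
    boundary_jitter_radius / boundary_jitter_prob : observations within the
        radius (lattice steps on the 4-neighbor graph) of a domain boundary
        are reassigned to the adjacent domain with this probability.
    merge : optional (a, b) pair of domain codes mapped to one.
    split : optional domain code split at its coordinate median.
    permute_labels : randomly permute the final label codes.
    """

    flip_rate: float = 0.0
    boundary_jitter_radius: float = 0.0
    boundary_jitter_prob: float = 0.0
    merge: tuple[int, int] | None = None
    split: int | None = None
    permute_labels: bool = False
    seed: int = 0
    method_id: str = "synthetic"
    config_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.flip_rate <= 1:
            raise ValueError("flip_rate must be in [0, 1]")
        if not 0 <= self.boundary_jitter_prob <= 1:
            raise ValueError("boundary_jitter_prob must be in [0, 1]")
        if self.boundary_jitter_radius < 0:
            raise ValueError("boundary_jitter_radius must be >= 0")

    def describe(self) -> str:
        parts = [f"flip{self.flip_rate:g}"]
        if self.boundary_jitter_prob > 0:
            parts.append(f"jit{self.boundary_jitter_radius:g}p{self.boundary_jitter_prob:g}")
        if self.merge is not None:
            parts.append(f"merge{self.merge[0]}-{self.merge[1]}")
        if self.split is not None:
            parts.append(f"split{self.split}")
        if self.permute_labels:
            parts.append("perm")
        return "_".join(parts)


def generate_tissue(
    layout: str = "layers",
    n_rows: int = 24,
    n_cols: int = 20,
    n_domains: int = 4,
    seed: int = 0,
) -> SyntheticTissue:
    """Square-lattice tissue with *n_domains* connected spatial domains.

    ``layers``: horizontal bands of near-equal height (a layered cortex);
    ``blocks``: a rectangular tiling as near-square as the domain count
    allows.  Deterministic given the seed (the layouts themselves are
    deterministic; the seed is recorded for provenance).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    coords = np.column_stack([cols.astype(float), rows.astype(float)])
    if layout == "layers":
        if n_domains > n_rows:
            raise ValueError(f"{n_domains} layers do not fit in {n_rows} rows")
        band_of_row = np.repeat(
            np.arange(n_domains), [len(b) for b in np.array_split(np.arange(n_rows), n_domains)]
        )
        labels = band_of_row[rows]
    elif layout == "blocks":
        pairs = [
            (a, n_domains // a)
            for a in range(1, n_domains + 1)
            if n_domains % a == 0 and a <= n_rows and n_domains // a <= n_cols
        ]
        if not pairs:
            raise ValueError(
                f"cannot tile a {n_rows}x{n_cols} grid into {n_domains} blocks"
            )
        a, b = min(pairs, key=lambda ab: abs(ab[0] - ab[1]))
        row_band = np.repeat(
            np.arange(a), [len(x) for x in np.array_split(np.arange(n_rows), a)]
        )
        col_band = np.repeat(
            np.arange(b), [len(x) for x in np.array_split(np.arange(n_cols), b)]
        )
        labels = row_band[rows] * b + col_band[cols]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    width = max(4, len(str(n_rows * n_cols)))
    ids = np.asarray([f"obs{i:0{width}d}" for i in range(n_rows * n_cols)], dtype=object)
    return SyntheticTissue(
        coords=coords,
        gt_labels=labels.astype(np.int64),
        observation_ids=ids,
        layout=layout,
        n_rows=n_rows,
        n_cols=n_cols,
        n_domains=n_domains,
        seed=seed,
    )


def _lattice_neighbors(tissue: SyntheticTissue) -> list[np.ndarray]:
    """4-neighbor adjacency on the lattice, by flat index."""
    nr, nc = tissue.n_rows, tissue.n_cols
    out = []
    for i in range(nr * nc):
        r, c = divmod(i, nc)
        nbrs = []
        if r > 0:
            nbrs.append(i - nc)
        if r < nr - 1:
            nbrs.append(i + nc)
        if c > 0:
            nbrs.append(i - 1)
        if c < nc - 1:
            nbrs.append(i + 1)
        out.append(np.asarray(nbrs, dtype=np.int64))
    return out


def _boundary_bfs(labels: np.ndarray, adjacency: list[np.ndarray]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Distance (lattice steps) to the nearest domain boundary, and the
    label of the domain on the other side of that boundary."""
    n = len(labels)
    dist = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    adj_label = np.full(n, -1, dtype=np.int64)
    queue: deque[int] = deque()
    for i in range(n):
        others = [labels[j] for j in adjacency[i] if labels[j] != labels[i]]
        if others:
            dist[i] = 0
            adj_label[i] = min(others)
            queue.append(i)
    while queue:
        i = queue.popleft()
        for j in adjacency[i]:
            if dist[j] > dist[i] + 1:
                dist[j] = dist[i] + 1
                adj_label[j] = adj_label[i]
                queue.append(j)
    return dist, adj_label


def perturb_labeling(tissue: SyntheticTissue, spec: NoiseSpec) -> SpatialLabeling:
    """One noisy base clustering of the tissue, per the noise spec.

    Perturbations apply in order: merge, split, boundary jitter, iid label
    flips, label permutation.
    """
    rng = np.random.default_rng(spec.seed)
    labels = tissue.gt_labels.copy()

    if spec.merge is not None:
        a, b = spec.merge
        present = np.unique(labels)
        if a not in present or b not in present:
            raise ValueError(f"merge domains {spec.merge} not present in the tissue")
        labels[labels == b] = a

    if spec.split is not None:
        d = spec.split
        members = np.flatnonzero(labels == d)
        if members.size == 0:
            raise ValueError(f"split domain {d} not present in the tissue")
        xy = tissue.coords[members]
        extent = xy.max(axis=0) - xy.min(axis=0)
        axis = 1 if extent[1] > extent[0] else 0  # tie -> x
        median = np.median(xy[:, axis])
        upper = members[xy[:, axis] > median]
        if upper.size and upper.size < members.size:
            labels[upper] = labels.max() + 1

    if spec.boundary_jitter_prob > 0:
        adjacency = _lattice_neighbors(tissue)
        dist, adj_label = _boundary_bfs(labels, adjacency)
        eligible = dist <= spec.boundary_jitter_radius
        hit = eligible & (rng.random(tissue.n_obs) < spec.boundary_jitter_prob)
        labels[hit] = adj_label[hit]

    if spec.flip_rate > 0:
        alphabet = np.unique(labels)
        if alphabet.size > 1:
            flip = rng.random(tissue.n_obs) < spec.flip_rate
            offsets = rng.integers(1, alphabet.size, size=tissue.n_obs)
            pos = np.searchsorted(alphabet, labels)
            flipped = alphabet[(pos + offsets) % alphabet.size]
            labels = np.where(flip, flipped, labels)

    if spec.permute_labels:
        alphabet = np.unique(labels)
        perm = rng.permutation(alphabet.size)
        pos = np.searchsorted(alphabet, labels)
        labels = perm[pos]

    return SpatialLabeling(
        observation_ids=tissue.observation_ids,
        coords=tissue.coords,
        labels=labels,
        method_id=spec.method_id,
        config_id=spec.config_id if spec.config_id is not None else spec.describe(),
        sample_id=f"synthetic_{tissue.seed}",
    )


def default_noise_specs(
    m: int,
    flip_rate: float = DEFAULT_FLIP_RATE,
    boundary_jitter_radius: float = DEFAULT_JITTER_RADIUS,
    boundary_jitter_prob: float = DEFAULT_JITTER_PROB,
    permute_labels: bool = True,
    seed: int = 0,
) -> list[NoiseSpec]:
    """M independent noise specs emulating M distinct methods."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=m)
    return [
        NoiseSpec(
            flip_rate=flip_rate,
            boundary_jitter_radius=boundary_jitter_radius,
            boundary_jitter_prob=boundary_jitter_prob,
            permute_labels=permute_labels,
            seed=int(s),
            method_id=f"sim{i:02d}",
        )
        for i, s in enumerate(seeds)
    ]


def granularity_specs(
    tissue: SyntheticTissue,
    k: int,
    m: int,
    flip_rate: float = DEFAULT_FLIP_RATE,
    permute_labels: bool = True,
    seed: int = 0,
) -> list[NoiseSpec]:
    """Specs for M base clusterings with exactly *k* clusters each.

    Emulates methods forced to a granularity one step away from the true
    domain count: at k = n_domains − 1 each method merges a (rotating)
    adjacent domain pair; at k = n_domains + 1 each splits a (rotating)
    domain at its median — so methods at the wrong granularity resolve it
    differently, while methods at the true granularity agree up to noise.
    """
    d = tissue.n_domains
    if k not in (d - 1, d, d + 1):
        raise ValueError(f"supported cluster counts are {d - 1}..{d + 1}, got {k}")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=m)
    specs = []
    for i, s in enumerate(seeds):
        merge = split = None
        if k == d - 1:
            a = i % (d - 1)
            merge = (a, a + 1)
        elif k == d + 1:
            split = i % d
        specs.append(
            NoiseSpec(
                flip_rate=flip_rate,
                merge=merge,
                split=split,
                permute_labels=permute_labels,
                seed=int(s),
                method_id=f"sim{i:02d}",
                config_id=f"k{k}",
            )
        )
    return specs


def generate_collection(
    tissue: SyntheticTissue, specs: list[NoiseSpec]
) -> tuple[LabelingCollection, SpatialLabeling]:
    """One perturbed labeling per spec, assembled into a collection, with
    the ground-truth labeling returned alongside."""
    if not specs:
        raise ValueError("need at least one noise spec")
    labelings = []
    for i, spec in enumerate(specs):
        if spec.method_id == "synthetic":
            spec = replace(spec, method_id=f"sim{i:02d}")
        labelings.append(perturb_labeling(tissue, spec))
    return build_collection(labelings), tissue.ground_truth()
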