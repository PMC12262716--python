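"""Standardized TSV/JSON I/O for spatial cluster labelings.

A *labeling* is one clustering result on a spatial sample: observation ids
(spots, cells or bins), their 2-D coordinates, and a categorical label per
observation, plus provenance (which method and configuration produced it).
Labelings from many methods are assembled into a :class:`LabelingCollection`
on a shared observation index — the input to all consensus and entropy
operations.

File dialect: tab-separated, UTF-8, header row required, lines starting with
``#`` ignored.  Labels file: ``obs_id<TAB>label``; coordinates file:
``obs_id<TAB>x<TAB>y``; optional metadata JSON:
``{"method": str, "config": str, "sample": str, "n_clusters": int}``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialLabeling",
    "LabelingCollection",
    "read_labeling",
    "write_labeling",
    "build_collection",
]

#: maximum per-axis disagreement tolerated between coordinate tables that
#: claim to describe the same sample
COORD_TOL = 1e-6


def _densify(raw_labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Recode arbitrary label values to dense ints 0..K-1.

    Codes are assigned in sorted order of the string form of the original
    labels, so densification is deterministic.  Returns (codes, alphabet)
    where ``alphabet[code]`` is the original label string.
    """
    strings = np.asarray([str(v) for v in raw_labels])
    alphabet = sorted(set(strings.tolist()))
    lookup = {lab: i for i, lab in enumerate(alphabet)}
    codes = np.fromiter((lookup[s] for s in strings), dtype=np.int64, count=len(strings))
    return codes, alphabet


@dataclass
class SpatialLabeling:
    """One clustering result over spatially located observations.

    Attributes
    ----------
    observation_ids : ndarray of str, shape (N,)
        Unique observation identifiers.
    coords : ndarray of float, shape (N, 2)
        (x, y) position of each observation; arbitrary but shared units.
    labels : ndarray of int, shape (N,)
        Dense categorical codes ``0..K-1``.
    alphabet : list of str
        Original label strings; ``alphabet[code]`` recovers them.
    method_id, config_id, sample_id : str
        Provenance of the labeling.
    """

    observation_ids: np.ndarray
    coords: np.ndarray
    labels: np.ndarray
    alphabet: list[str] = field(default_factory=list)
    method_id: str = "unknown"
    config_id: str = "default"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.observation_ids = np.asarray(self.observation_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        n = len(self.observation_ids)
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} observations"
            )
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} observations")
        uniq, counts = np.unique(self.observation_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise ValueError(f"duplicate observation id: {dup!r}")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinate encountered")
        if self.labels.dtype.kind not in "iu":
            codes, alphabet = _densify(self.labels)
            self.labels = codes
            if not self.alphabet:
                self.alphabet = alphabet
        else:
            self.labels = self.labels.astype(np.int64)
            if not self.alphabet:
                self.alphabet = [str(v) for v in range(int(self.labels.max()) + 1)] if n else []
        if n == 0:
            raise ValueError("empty labeling")

    @property
    def n_obs(self) -> int:
        return len(self.observation_ids)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def label_strings(self) -> np.ndarray:
        """Labels mapped back to their original string values."""
        return np.asarray([self.alphabet[c] for c in self.labels], dtype=object)


@dataclass
class LabelingCollection:
    """M base clusterings over N shared observations.

    ``label_matrix`` is N×M with per-column dense codes ``0..K_m-1``;
    ``provenance`` holds one ``(method_id, config_id)`` pair per column.
    """

    observation_ids: np.ndarray
    coords: np.ndarray
    label_matrix: np.ndarray
    provenance: list[tuple[str, str]]
    dropped_observations: list[str] = field(default_factory=list)
    sample_id: str = ""

    @property
    def n_obs(self) -> int:
        return self.label_matrix.shape[0]

    @property
    def n_labelings(self) -> int:
        return self.label_matrix.shape[1]

    def column(self, m: int) -> np.ndarray:
        return self.label_matrix[:, m]

    def cluster_counts(self) -> np.ndarray:
        """Number of distinct labels in each column."""
        return np.asarray(
            [len(np.unique(self.label_matrix[:, m])) for m in range(self.n_labelings)]
        )

    def subset_columns(self, cols) -> "LabelingCollection":
        cols = list(cols)
        mat = self.label_matrix[:, cols]
        # re-densify: a column subset never changes codes, but dropping
        # observations elsewhere may have left gaps upstream
        dense = np.empty_like(mat)
        for j in range(mat.shape[1]):
            _, dense[:, j] = np.unique(mat[:, j], return_inverse=True)
        return LabelingCollection(
            observation_ids=self.observation_ids,
            coords=self.coords,
            label_matrix=dense,
            provenance=[self.provenance[c] for c in cols],
            dropped_observations=list(self.dropped_observations),
            sample_id=self.sample_id,
        )

    def column_labeling(self, m: int) -> SpatialLabeling:
        """View column *m* as a stand-alone :class:`SpatialLabeling`."""
        method, config = self.provenance[m]
        return SpatialLabeling(
            observation_ids=self.observation_ids,
            coords=self.coords,
            labels=self.label_matrix[:, m],
            method_id=method,
            config_id=config,
            sample_id=self.sample_id,
        )


def _read_tsv(path: str | Path, expected_cols: int, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")
    if df.shape[1] < expected_cols:
        raise ValueError(
            f"{what} file {path} has {df.shape[1]} columns, expected {expected_cols}"
        )
    return df


def read_labeling(
    labels_path: str | Path,
    coords_path: str | Path,
    meta_path: str | Path | None = None,
) -> SpatialLabeling:
    """Read a labeling from the standardized TSV/JSON files.

    Ids present in the labels file but absent from the coordinates file (or
    vice versa) are dropped with a logged warning; duplicate ids, non-numeric
    coordinates, or an empty intersection raise ``ValueError``.
    """
    ldf = _read_tsv(labels_path, 2, "labels")
    cdf = _read_tsv(coords_path, 3, "coords")
    lids = ldf.iloc[:, 0].astype(str)
    cids = cdf.iloc[:, 0].astype(str)
    for name, ids in (("labels", lids), ("coords", cids)):
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate id {dup.iloc[0]!r} in {name} file")
    try:
        xy = cdf.iloc[:, 1:3].astype(float)
    except ValueError as exc:
        bad = cdf.index[
            pd.to_numeric(cdf.iloc[:, 1], errors="coerce").isna()
            | pd.to_numeric(cdf.iloc[:, 2], errors="coerce").isna()
        ]
        row = int(bad[0]) + 2 if len(bad) else -1  # +2: header + 1-based
        raise ValueError(f"non-numeric coordinate at row {row} of {coords_path}") from exc

    lset, cset = set(lids), set(cids)
    common = lset & cset
    if not common:
        raise ValueError("labels and coordinates share no observation ids")
    n_dropped = len(lset ^ cset)
    if n_dropped:
        logger.warning(
            "%d observation id(s) present in only one of labels/coords were dropped",
            n_dropped,
        )
    keep = sorted(common)
    lab = pd.Series(ldf.iloc[:, 1].values, index=lids).loc[keep]
    pos = pd.DataFrame(xy.values, index=cids).loc[keep]

    method, config, sample = "unknown", "default", ""
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text(encoding="utf-8"))
        method = str(meta.get("method", method))
        config = str(meta.get("config", config))
        sample = str(meta.get("sample", sample))
    return SpatialLabeling(
        observation_ids=np.asarray(keep, dtype=object),
        coords=pos.values,
        labels=lab.values,
        method_id=method,
        config_id=config,
        sample_id=sample,
    )


def write_labeling(
    labeling: SpatialLabeling,
    labels_path: str | Path,
    coords_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> None:
    """Write a labeling back out in the same TSV/JSON dialect."""
    pd.DataFrame(
        {"obs_id": labeling.observation_ids, "label": labeling.label_strings()}
    ).to_csv(labels_path, sep="\t", index=False, encoding="utf-8")
    if coords_path is not None:
        pd.DataFrame(
            {
                "obs_id": labeling.observation_ids,
                "x": labeling.coords[:, 0],
                "y": labeling.coords[:, 1],
            }
        ).to_csv(coords_path, sep="\t", index=False, encoding="utf-8")
    if meta_path is not None:
        Path(meta_path).write_text(
            json.dumps(
                {
                    "method": labeling.method_id,
                    "config": labeling.config_id,
                    "sample": labeling.sample_id,
                    "n_clusters": labeling.n_clusters,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )


def build_collection(labelings: list[SpatialLabeling]) -> LabelingCollection:
    """Assemble labelings into a collection on the intersection of their ids.

    The observation index is the lexicographically sorted intersection of all
    id sets (consensus algorithms need a complete matrix, so observations a
    method discarded are dropped and recorded).  Coordinates are taken from
    the first labeling and must agree across labelings within ``COORD_TOL``
    per axis.
    """
    if not labelings:
        raise ValueError("need at least one labeling")
    samples = {l.sample_id for l in labelings if l.sample_id}
    if len(samples) > 1:
        raise ValueError(f"labelings come from different samples: {sorted(samples)}")

    id_sets = [set(l.observation_ids.astype(str).tolist()) for l in labelings]
    common = set.intersection(*id_sets)
    if not common:
        raise ValueError("labelings have an empty observation-id intersection")
    keep = np.asarray(sorted(common), dtype=object)
    dropped = sorted(set.union(*id_sets) - common)

    n = len(keep)
    mat = np.empty((n, len(labelings)), dtype=np.int64)
    coords_ref: np.ndarray | None = None
    provenance: list[tuple[str, str]] = []
    for m, lab in enumerate(labelings):
        order = pd.Series(
            np.arange(lab.n_obs), index=lab.observation_ids.astype(str)
        ).loc[keep].values
        coords = lab.coords[order]
        if coords_ref is None:
            coords_ref = coords
        else:
            diff = np.abs(coords - coords_ref)
            if (diff > COORD_TOL).any():
                i = int(np.argwhere((diff > COORD_TOL).any(axis=1))[0, 0])
                raise ValueError(
                    f"coordinate disagreement at observation {keep[i]!r} "
                    f"between labeling 0 and labeling {m}"
                )
        # densify after subsetting: dropped observations may have removed codes
        _, dense = np.unique(lab.labels[order], return_inverse=True)
        mat[:, m] = dense
        provenance.append((lab.method_id, lab.config_id))

    return LabelingCollection(
        observation_ids=keep,
        coords=coords_ref,
        label_matrix=mat,
        provenance=provenance,
        dropped_observations=dropped,
        sample_id=next(iter(samples)) if samples else "",
    )
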