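"""Habitat delineation from physicochemical depth profiles.

A stratified water column is partitioned into discrete habitats by
agglomerative complete-linkage clustering of the depth x variable matrix
(variables standardized first), and measured profiles can be interpolated to
arbitrary depths for downstream correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import read_table, write_table

__all__ = [
    "EnvProfile",
    "HabitatPartition",
    "cluster_depths",
    "interpolate_profile",
    "DEFAULT_HABITAT_LABELS",
]

#: Canonical limnological layer names, shallow to deep, used when k == 3.
DEFAULT_HABITAT_LABELS = ("mixolimnion", "chemocline", "monimolimnion")


@dataclass
class EnvProfile:
    """Environmental variables measured at discrete depths.

    ``data`` is indexed by depth (m, strictly increasing), one column per
    variable; NaN marks a missing measurement (e.g. below detection).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        depths = np.asarray(self.data.index, dtype=float)
        if len(depths) == 0:
            raise ValueError("profile has no depths")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        self.data.index = depths
        self.data.index.name = "depth_m"

    @property
    def depths(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnvProfile":
        df = read_table(path)
        if "depth_m" not in df.columns:
            raise ValueError(f"{path}: missing required column 'depth_m'")
        return cls(df.set_index("depth_m"))

    def to_tsv(self, path: str | Path, **meta) -> None:
        write_table(self.data.reset_index(), path, metadata=meta)


@dataclass
class HabitatPartition:
    """Assignment of sampled depths to k habitats.

    ``labels`` are ordered by increasing mean member depth; ``merge_history``
    holds the complete-linkage merge heights (one per agglomeration step,
    non-decreasing) for verification against an independent linkage oracle.
    """

    k: int
    assignment: dict[float, str]
    labels: tuple[str, ...]
    merge_history: list[float] = field(default_factory=list)

    def habitat_for_depth(self, depth: float) -> str:
        try:
            return self.assignment[float(depth)]
        except KeyError:
            raise KeyError(f"depth {depth} m is not part of the partition") from None

    def members(self, label: str) -> list[float]:
        return sorted(d for d, lab in self.assignment.items() if lab == label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for depth in sorted(self.assignment):
            label = self.assignment[depth]
            rows.append(
                {
                    "depth_m": depth,
                    "cluster_index": self.labels.index(label),
                    "habitat_label": label,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path, **meta) -> None:
        write_table(self.to_frame(), path, metadata=meta)


def _pairwise_complete_distances(values: np.ndarray) -> np.ndarray:
    """Euclidean distances between rows, ignoring missing coordinates.

    Follows the R ``dist`` convention: the squared sum over observed
    coordinates is rescaled by p_total / p_observed before the square root,
    so rows with gaps remain comparable to complete rows.
    """
    n, p = values.shape
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(values[i]) | np.isnan(values[j]))
            used = int(mask.sum())
            if used == 0:
                raise ValueError(
                    f"rows {i} and {j} share no observed variables; "
                    "cannot compute a distance"
                )
            diff = values[i, mask] - values[j, mask]
            dist[i, j] = dist[j, i] = np.sqrt((p / used) * float(diff @ diff))
    return dist


def _complete_linkage(dist: np.ndarray, k: int) -> tuple[list[tuple[int, ...]], list[float]]:
    """Agglomerate rows by complete linkage down to k clusters.

    Ties on merge distance are broken toward the lexicographically smallest
    pair of member tuples, making the procedure fully deterministic. Returns
    the member tuples of the k final clusters and the full merge-height
    history (agglomeration continues past k only to record heights).
    """
    clusters: list[tuple[int, ...]] = [(i,) for i in range(dist.shape[0])]
    heights: list[float] = []
    at_k: list[tuple[int, ...]] | None = [tuple(c) for c in clusters] if k == len(clusters) else None

    def cluster_dist(a: tuple[int, ...], b: tuple[int, ...]) -> float:
        return max(dist[i, j] for i in a for j in b)

    while len(clusters) > 1:
        best: tuple[float, tuple[int, ...], tuple[int, ...]] | None = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                a, b = clusters[ai], clusters[bi]
                d = cluster_dist(a, b)
                key = (d, min(a, b), max(a, b))
                if best is None or key < (best[0], min(best[1], best[2]), max(best[1], best[2])):
                    best = (d, a, b)
        assert best is not None
        d, a, b = best
        heights.append(d)
        clusters = [c for c in clusters if c is not a and c is not b]
        clusters.append(tuple(sorted(a + b)))
        if len(clusters) == k:
            at_k = [tuple(c) for c in clusters]
    if at_k is None:  # k == n handled above; k < 1 rejected by caller
        at_k = [tuple(c) for c in clusters]
    return at_k, heights


def cluster_depths(
    profile: EnvProfile,
    k: int = 3,
    labels: Sequence[str] | None = None,
) -> HabitatPartition:
    """Partition sampled depths into k habitats.

    Each variable is standardized to zero mean / unit variance across depths
    (so high-magnitude solutes do not dominate), pairwise euclidean distances
    between depth rows are clustered by complete linkage, and the tree is cut
    into k clusters. Cluster labels are ordered by increasing mean member
    depth; with k = 3 the canonical names mixolimnion / chemocline /
    monimolimnion are used.
    """
    data = profile.data.astype(float)
    n = len(data)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of depths ({n})")
    if n < 2 or data.shape[1] < 1:
        raise ValueError("clustering needs at least 2 depths and 1 variable")

    keep = []
    for col in data.columns:
        col_values = data[col]
        if col_values.isna().all():
            raise ValueError(f"variable {col!r} is entirely missing")
        if np.nanstd(col_values.to_numpy()) == 0:
            warnings.warn(f"dropping constant variable {col!r}", stacklevel=2)
            continue
        keep.append(col)
    if not keep:
        raise ValueError("no variable with nonzero variance")
    values = data[keep].to_numpy()
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    standardized = (values - mean) / sd

    dist = _pairwise_complete_distances(standardized)
    member_sets, heights = _complete_linkage(dist, k)

    depths = profile.depths
    member_sets = sorted(member_sets, key=lambda c: float(np.mean(depths[list(c)])))
    if labels is None:
        labels = DEFAULT_HABITAT_LABELS if k == 3 else tuple(f"habitat_{i + 1}" for i in range(k))
    labels = tuple(labels)
    if len(labels) != k:
        raise ValueError(f"{len(labels)} labels given for k={k} clusters")

    assignment: dict[float, str] = {}
    for label, members in zip(labels, member_sets):
        for idx in members:
            assignment[float(depths[idx])] = label
    return HabitatPartition(k=k, assignment=assignment, labels=labels, merge_history=heights)


def interpolate_profile(profile: EnvProfile, query_depths: Sequence[float]) -> EnvProfile:
    """Piecewise-linear interpolation of every variable at new depths.

    Exact at measured depths. Missing values are bridged by interpolating
    between the nearest observed depths of that variable. Queries outside the
    measured range raise (no extrapolation).
    """
    query = np.asarray(sorted(set(float(q) for q in query_depths)), dtype=float)
    if query.size == 0:
        raise ValueError("no query depths given")
    depths = profile.depths
    if query.min() < depths.min() or query.max() > depths.max():
        raise ValueError(
            f"query depths must lie within the measured range "
            f"[{depths.min()}, {depths.max()}] m; no extrapolation"
        )
    out = {}
    for col in profile.variables:
        y = profile.data[col].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        if mask.sum() == 0:
            out[col] = np.full(query.shape, np.nan)
            continue
        xs, ys = depths[mask], y[mask]
        vals = np.interp(query, xs, ys)
        # do not extrapolate a variable beyond its own observed support
        vals[(query < xs.min()) | (query > xs.max())] = np.nan
        out[col] = vals
    return EnvProfile(pd.DataFrame(out, index=query))
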