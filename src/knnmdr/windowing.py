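"""Marker windows and per-window squared-distance matrices.

The interaction scan operates on *windows* — contiguous, non-overlapping
marker-index intervals.  For each window a squared-distance matrix
between individuals is precomputed once; multi-window models then
combine matrices by elementwise addition, which is exact for metrics
without cross-window terms (normalized Euclidean, binary).

Squared distances are the stored and combined quantity throughout:
taking square roots is never needed to rank neighbors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "METRICS",
    "WindowPartition",
    "WindowDistanceSet",
    "make_windows",
    "make_windows_from_boundaries",
    "window_squared_distances",
    "compute_distance_set",
    "combine_window_distances",
    "write_window_partition",
    "read_window_partition",
]

METRICS = ("normalized_euclidean", "mahalanobis", "binary")


@dataclasses.dataclass(frozen=True)
class WindowPartition:
    """Ordered list of half-open marker-index intervals ``[start, end)``."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.intervals:
            if end <= start or start < 0:
                raise ValueError(f"empty or negative window [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("windows must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_windows(self) -> int:
        return len(self.intervals)

    def sizes(self) -> list[int]:
        return [end - start for start, end in self.intervals]

    def markers(self, window_id: int) -> np.ndarray:
        start, end = self.intervals[window_id]
        return np.arange(start, end)

    def markers_of(self, window_ids: Iterable[int]) -> np.ndarray:
        """Pooled marker indices of several windows, in ascending order."""
        return np.concatenate([self.markers(w) for w in sorted(window_ids)])

    def window_of_marker(self, marker_index: int) -> int | None:
        for w, (start, end) in enumerate(self.intervals):
            if start <= marker_index < end:
                return w
        return None


def make_windows(n_markers: int, window_size: int) -> WindowPartition:
    """Split ``0..n_markers`` into consecutive windows of ``window_size``.

    A trailing remainder window of size ``n_markers % window_size`` is
    appended when the division is not exact, so every marker is covered.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if n_markers < window_size:
        raise ValueError("window_size exceeds the number of markers")
    edges = list(range(0, n_markers + 1, window_size))
    if edges[-1] != n_markers:
        edges.append(n_markers)
    return WindowPartition(tuple(zip(edges[:-1], edges[1:])))


def make_windows_from_boundaries(boundaries: Sequence[int]) -> WindowPartition:
    """Build windows from an explicit strictly increasing boundary list."""
    bounds = list(boundaries)
    if len(bounds) < 2:
        raise ValueError("need at least two boundaries")
    if any(b <= a for a, b in zip(bounds[:-1], bounds[1:])):
        raise ValueError("boundaries must be strictly increasing")
    return WindowPartition(tuple(zip(bounds[:-1], bounds[1:])))


@dataclasses.dataclass
class WindowDistanceSet:
    """One ``n_ind x n_ind`` squared-distance matrix per window."""

    matrices: np.ndarray  # (n_windows, n_ind, n_ind)
    metric: str
    partition: WindowPartition | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (W, n, n)")

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.matrices.shape[1]


def _scaled_columns(
    values: np.ndarray,
    window: tuple[int, int],
    weights: np.ndarray | None,
    variances: np.ndarray | None,
    dtype: type,
) -> np.ndarray:
    start, end = window
    if start < 0 or end > values.shape[1] or end <= start:
        raise ValueError(f"window [{start}, {end}) out of bounds")
    X = values[:, start:end].astype(dtype)
    s2 = X.var(axis=0) if variances is None else np.asarray(variances, dtype=float)
    if s2.shape != (end - start,):
        raise ValueError("variances must have one entry per in-window marker")
    w = np.ones(end - start) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (end - start,):
        raise ValueError("weights must have one entry per in-window marker")
    # monomorphic markers contribute 0 by convention
    scale = np.where(s2 > 0, np.sqrt(w / np.where(s2 > 0, s2, 1.0)), 0.0)
    return X * scale


def window_squared_distances(
    values: np.ndarray,
    window: tuple[int, int],
    metric: str = "normalized_euclidean",
    weights: np.ndarray | None = None,
    variances: np.ndarray | None = None,
    ridge: float = 0.0,
    dtype: type = np.float64,
) -> np.ndarray:
    """Squared distances between all pairs of individuals over one window.

    ``normalized_euclidean``:
        ``d2(i, j) = sum_m w_m (g_im - g_jm)^2 / s2_m`` with ``s2_m`` the
        sample variance of marker *m* (whole sample; phenotype-free).
    ``mahalanobis``:
        full quadratic form of the standardized differences with the
        inverse in-window marker correlation matrix (optionally ridged).
    ``binary``:
        squared number of differing alleles per marker (0, 1 or 2),
        variance-normalized — identical to ``normalized_euclidean`` on
        biallelic 0/1/2 counts, kept as an explicit metric because it
        also generalizes to non-count codings.

    *variances* may be supplied to override the per-marker normalization
    (e.g. unit variances for hand calculations).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    X = _scaled_columns(values, window, weights, variances, dtype)
    if metric in ("normalized_euclidean", "binary"):
        d2 = cdist(X, X, "sqeuclidean")
    else:
        keep = X.var(axis=0) > 0
        Z = X[:, keep]
        if Z.shape[1] == 0:
            d2 = np.zeros((X.shape[0], X.shape[0]))
        else:
            R = np.corrcoef(Z, rowvar=False).reshape(Z.shape[1], Z.shape[1])
            if ridge > 0:
                R = R + ridge * np.eye(R.shape[0])
            try:
                Rinv = np.linalg.inv(R)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular in-window correlation matrix; pass ridge>0 "
                    "(e.g. ridge=1e-6) to regularize"
                ) from exc
            d2 = cdist(Z, Z, "mahalanobis", VI=Rinv) ** 2
    d2 = np.asarray(d2, dtype=dtype)
    np.fill_diagonal(d2, 0.0)
    return (d2 + d2.T) / 2.0


def compute_distance_set(
    values: np.ndarray,
    partition: WindowPartition,
    metric: str = "normalized_euclidean",
    weights: np.ndarray | None = None,
    ridge: float = 0.0,
    dtype: type = np.float64,
) -> WindowDistanceSet:
    """Precompute the squared-distance matrix of every window."""
    n = values.shape[0]
    mats = np.empty((partition.n_windows, n, n), dtype=dtype)
    for w, (start, end) in enumerate(partition.intervals):
        wts = None if weights is None else weights[start:end]
        mats[w] = window_squared_distances(
            values, (start, end), metric=metric, weights=wts, dtype=dtype
        )
    return WindowDistanceSet(mats, metric, partition)


def combine_window_distances(
    dset: WindowDistanceSet, window_ids: Sequence[int]
) -> np.ndarray:
    """Elementwise sum of the selected per-window squared distances.

    Exactly equals a one-pass computation over the pooled markers for
    metrics without cross-window terms (normalized Euclidean, binary).
    """
    ids = list(window_ids)
    if len(ids) == 0:
        raise ValueError("window_ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicated window id in {ids}")
    if min(ids) < 0 or max(ids) >= dset.n_windows:
        raise ValueError(f"window id out of range in {ids}")
    if len(ids) == 1:
        return dset.matrices[ids[0]]
    return dset.matrices[ids].sum(axis=0)


def write_window_partition(
    path: str | Path, partition: WindowPartition, chromosome: str = "."
) -> None:
    """Write windows as BED-like TSV: chrom, start, end (0-based half-open), id."""
    with open(path, "w") as fh:
        for w, (start, end) in enumerate(partition.intervals):
            fh.write(f"{chromosome}\t{start}\t{end}\tw{w}\n")


def read_window_partition(path: str | Path) -> WindowPartition:
    intervals = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            intervals.append((int(fields[1]), int(fields[2])))
    return WindowPartition(tuple(intervals))
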