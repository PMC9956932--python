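"""Deterministic DBSCAN over a precomputed distance matrix.

The variant is pinned down exactly so results are reproducible and
order-independent:

* a point's neighbourhood is the closed ball ``d <= r`` and includes the
  point itself, so ``Nmin = 1`` makes every point a core point;
* clusters are the connected components of core points under mutual
  r-reachability;
* a border point (non-core within r of at least one core point) joins the
  cluster of the lowest-index such core point;
* cluster ids 1..K are assigned in order of the lowest point index each
  cluster contains; noise points get -1.

Plain O(n^2) neighbourhood scan — batches are small enough that indexed
variants buy nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NOISE = -1
STD_OUTLIER = -2  # used downstream for std-stage calls, never by dbscan itself


@dataclass
class DBSCANParams:
    """Neighbourhood radius ``r`` (same units as the distance matrix) and the
    minimum neighbour count ``nmin`` (self included) that makes a core point."""

    r: float
    nmin: int

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("r must be > 0")
        if not (isinstance(self.nmin, (int, np.integer)) and self.nmin >= 1):
            raise ValueError("nmin must be an integer >= 1")


@dataclass
class ClusterLabeling:
    """Per-point labels: 1..K for compact clusters, -1 for noise."""

    labels: np.ndarray
    core_flags: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.core_flags = np.asarray(self.core_flags, dtype=bool)
        if self.labels.shape != self.core_flags.shape:
            raise ValueError("labels and core_flags must align")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0)) if np.any(self.labels > 0) else 0

    def cluster_members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def noise_points(self) -> np.ndarray:
        return np.flatnonzero(self.labels == NOISE)


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def dbscan(D: np.ndarray, params: DBSCANParams) -> ClusterLabeling:
    """Cluster points given their pairwise distances; see module docstring
    for the exact variant."""
    D = _validate_distance_matrix(D)
    n = D.shape[0]
    neighbours = D <= params.r  # closed ball; diagonal True (self-inclusion)
    core = neighbours.sum(axis=1) >= params.nmin

    labels = np.zeros(n, dtype=int)  # 0 = unassigned
    next_id = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != 0:
            continue
        next_id += 1
        # breadth-first expansion over mutually r-reachable core points
        stack = [seed]
        labels[seed] = next_id
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(neighbours[i] & core):
                if labels[j] == 0:
                    labels[j] = next_id
                    stack.append(j)

    for i in np.flatnonzero(~core):
        reachable_cores = np.flatnonzero(neighbours[i] & core)
        labels[i] = labels[reachable_cores[0]] if reachable_cores.size else NOISE

    return ClusterLabeling(labels=_renumber(labels), core_flags=core)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..K by the lowest point index each contains."""
    out = labels.copy()
    order: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab > 0 and lab not in order:
            order[lab] = len(order) + 1
    for i, lab in enumerate(labels):
        if lab > 0:
            out[i] = order[lab]
    return out


def count_outliers(labeling: ClusterLabeling) -> int:
    """Number of noise points — the per-batch count of DE candidates."""
    return int(np.sum(labeling.labels == NOISE))
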