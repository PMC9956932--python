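"""Pairwise distance matrices over 2-D point sets.

Five dissimilarities are supported: Euclidean, cityblock, Chebyshev,
Minkowski with any p > 0 (fractional p included — not a metric, but DBSCAN
only needs a symmetric dissimilarity), and Mahalanobis. The Mahalanobis
covariance is by default estimated from the points of the batch being
clustered, which adapts the neighbourhoods to the oblong cloud that equally
expressed genes form along the equivalence line; an identity mode (plain
Euclidean check) and a global mode (covariance supplied from all genes) are
available for sensitivity analysis.

Point sets are small (batches of at most ~1022 genes), so dense n x n
matrices computed by direct broadcasting are used throughout; no spatial
indexing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METRIC_NAMES = ("euclidean", "cityblock", "chebyshev", "minkowski", "mahalanobis")
COVARIANCE_MODES = ("per_batch", "global", "identity")


@dataclass
class MetricSpec:
    """Which dissimilarity to use, with its metric-specific knobs.

    ``p`` applies to Minkowski only; ``covariance_mode`` and ``ridge`` to
    Mahalanobis only. ``ridge=None`` selects an automatic regulariser of
    1e-8 x trace(C)/2 so near-singular batch clouds never abort a run.
    """

    name: str = "euclidean"
    p: float = 2.0
    covariance_mode: str = "per_batch"
    ridge: float | None = None

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}; expected one of {METRIC_NAMES}")
        if self.name == "minkowski" and not self.p > 0:
            raise ValueError("minkowski requires p > 0")
        if self.covariance_mode not in COVARIANCE_MODES:
            raise ValueError(f"unknown covariance mode {self.covariance_mode!r}")
        if self.ridge is not None and self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def to_dict(self) -> dict:
        d = {"metric": self.name}
        if self.name == "minkowski":
            d["minkowski_p"] = self.p
        if self.name == "mahalanobis":
            d["covariance_mode"] = self.covariance_mode
            d["ridge"] = "auto" if self.ridge is None else self.ridge
        return d


def estimate_covariance(points: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Sample covariance (n-1 denominator) of 2-D points, plus ridge x I.

    Requires at least 3 points; positive definite whenever ridge > 0.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an n x 2 matrix")
    if points.shape[0] < 3:
        raise ValueError(
            f"covariance estimation needs at least 3 points, got {points.shape[0]}"
        )
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    C = np.cov(points, rowvar=False, ddof=1)
    return C + ridge * np.eye(2)


def _auto_ridge(C: np.ndarray) -> float:
    return 1e-8 * np.trace(C) / 2.0


def pairwise_distances(
    points: np.ndarray,
    spec: MetricSpec,
    global_covariance: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric n x n dissimilarity matrix over 2-D points under ``spec``.

    ``global_covariance`` must be supplied when ``spec`` is Mahalanobis with
    ``covariance_mode="global"``; it is ignored otherwise.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an n x 2 matrix")
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")

    diff = points[:, None, :] - points[None, :, :]  # n x n x 2
    name = spec.name
    if name == "euclidean":
        D = np.sqrt(np.sum(diff**2, axis=-1))
    elif name == "cityblock":
        D = np.sum(np.abs(diff), axis=-1)
    elif name == "chebyshev":
        D = np.max(np.abs(diff), axis=-1)
    elif name == "minkowski":
        D = np.sum(np.abs(diff) ** spec.p, axis=-1) ** (1.0 / spec.p)
    elif name == "mahalanobis":
        D = _mahalanobis(points, diff, spec, global_covariance)
    else:  # pragma: no cover - guarded by MetricSpec
        raise AssertionError(name)

    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def _mahalanobis(
    points: np.ndarray,
    diff: np.ndarray,
    spec: MetricSpec,
    global_covariance: np.ndarray | None,
) -> np.ndarray:
    mode = spec.covariance_mode
    if mode == "identity":
        C = np.eye(2)
    elif mode == "global":
        if global_covariance is None:
            raise ValueError("covariance_mode='global' requires global_covariance")
        C = np.asarray(global_covariance, dtype=float)
    else:
        C = estimate_covariance(points, ridge=0.0)
    ridge = _auto_ridge(C) if spec.ridge is None else spec.ridge
    C = C + ridge * np.eye(2)
    det = C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]
    if det <= 0 or not np.isfinite(det):
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; set ridge > 0 (or leave ridge=None "
            "for the automatic regulariser)"
        )
    Cinv = np.array([[C[1, 1], -C[0, 1]], [-C[1, 0], C[0, 0]]]) / det
    d2 = np.einsum("ijk,kl,ijl->ij", diff, Cinv, diff)
    return np.sqrt(np.maximum(d2, 0.0))
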