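"""Hybrid tumor segmentation: weighted ranking k-means init + fuzzy c-means.

The segmenter clusters per-pixel features in a weighted scalar projection:
each pixel contributes u = sum_i w_i x_i over its features (intensity and,
by default, a local mean).  Initial centroids come from an adaptive k-means
step — sort the weighted points, split them into k contiguous equal-size
blocks and take block means — which is deterministic and already roughly
ordered by intensity.  Fuzzy c-means with Euclidean distance then refines
centroids and memberships until the centroids stop moving.  The tumor
cluster is the one with the highest mean source intensity (contrast-bearing
tumors are hyperintense in the phantoms and in enhanced acquisitions);
callers can override the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import DegenerateInputError, ParameterError, ShapeError

__all__ = [
    "WeightedPoints",
    "ClusterModel",
    "SegmentationResult",
    "weighted_points",
    "akmc_init",
    "fkcm_iterate",
    "segment",
]

#: default per-feature weights for (intensity, local mean)
DEFAULT_FEATURE_WEIGHTS = (1.0, 0.5)


@dataclass
class WeightedPoints:
    """Scalar weighted projections u_j = sum_i W_i X_ij of the feature rows."""

    values: np.ndarray  # (n, d) original features
    weights: np.ndarray  # (d,)
    u: np.ndarray  # (n,) weighted points
    order: np.ndarray  # argsort of u


@dataclass
class ClusterModel:
    """Fuzzy clustering state: centroids, memberships and the objective trace."""

    k: int
    centroids: np.ndarray  # (k,)
    memberships: np.ndarray  # (n, k), rows sum to 1
    m: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class SegmentationResult:
    label_map: np.ndarray  # (H, W) int cluster labels
    tumor_mask: np.ndarray  # (H, W) bool
    tumor_cluster_id: int
    model: ClusterModel


def weighted_points(values: np.ndarray, weights) -> WeightedPoints:
    """Project feature rows onto their weighted sum and rank them."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]  # a list of scalars: single feature per point
    elif values.ndim != 2:
        raise ShapeError("values must be (n,) or (n, d)")
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if np.any(weights <= 0):
        raise ParameterError("feature weights must be positive")
    if weights.size != values.shape[1]:
        raise ShapeError("one weight per feature required")
    u = values @ weights
    return WeightedPoints(values=values, weights=weights, u=u, order=np.argsort(u, kind="stable"))


def akmc_init(points: WeightedPoints, k: int) -> np.ndarray:
    """Deterministic centroids: sort u, split into k contiguous blocks, take means.

    When n is not divisible by k the remainder is spread one extra point per
    leading block.
    """
    u = points.u
    n = u.size
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n:
        raise ParameterError("k may not exceed the number of points")
    su = u[points.order]
    base, rem = divmod(n, k)
    sizes = np.full(k, base)
    sizes[:rem] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return np.array([su[bounds[i] : bounds[i + 1]].mean() for i in range(k)])


def fkcm_iterate(
    points: WeightedPoints,
    init_centroids: np.ndarray,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> ClusterModel:
    """Fuzzy c-means on the weighted points with Euclidean distance.

    Alternates membership and centroid updates, recording the objective
    J = sum_ik u_ik^m d_ik^2 after each round; stops when the largest
    centroid shift falls below ``tol``.  A point coinciding with a centroid
    gets hard membership 1 there (the documented degenerate convention).
    """
    if m <= 1:
        raise ParameterError("fuzzifier m must be > 1")
    u = points.u[:, None]  # (n, 1)
    c = np.asarray(init_centroids, dtype=float).copy()
    k = c.size
    if k == 1:
        memberships = np.ones((u.size, 1))
        c = np.array([points.u.mean()])
        return ClusterModel(k=1, centroids=c, memberships=memberships, m=m, objective_trace=[0.0])

    trace: list[float] = []
    converged = False
    memberships = np.zeros((u.size, k))
    for _ in range(max_iter):
        d2 = (u - c[None, :]) ** 2  # (n, k)
        zero = d2 < 1e-300
        # membership u_ik = d_ik^{-2/(m-1)} / sum_j d_ij^{-2/(m-1)}
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            memberships = inv / inv.sum(axis=1, keepdims=True)
        row_zero = zero.any(axis=1)
        if row_zero.any():
            memberships[row_zero] = 0.0
            hard = d2[row_zero].argmin(axis=1)
            memberships[np.nonzero(row_zero)[0], hard] = 1.0
        um = memberships**m
        c_new = (um * u).sum(axis=0) / um.sum(axis=0)
        trace.append(float((um * (u - c_new[None, :]) ** 2).sum()))
        shift = np.abs(c_new - c).max()
        c = c_new
        if shift < tol:
            converged = True
            break
    return ClusterModel(
        k=k, centroids=c, memberships=memberships, m=m, objective_trace=trace, converged=converged
    )


def segment(
    fused: np.ndarray,
    k: int = 4,
    *,
    feature_weights=DEFAULT_FEATURE_WEIGHTS,
    local_mean: bool = True,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    tumor_cluster: int | None = None,
) -> SegmentationResult:
    """Segment a fused [0,1] image into k clusters and extract the tumor mask.

    Per-pixel features are (intensity, 3x3 local mean) by default, projected
    through ``feature_weights``.  The tumor cluster defaults to the one whose
    member pixels have the highest mean intensity; pass ``tumor_cluster`` to
    override.
    """
    fused = np.asarray(fused, dtype=float)
    if fused.ndim != 2:
        raise ShapeError("expected a 2-D grid")
    if np.unique(fused).size <= k:
        raise DegenerateInputError(
            f"image has at most {k} distinct intensity levels; nothing to cluster at k={k}"
        )
    feats = [fused.ravel()]
    weights = [feature_weights[0]]
    if local_mean:
        feats.append(uniform_filter(fused, size=3, mode="reflect").ravel())
        weights.append(feature_weights[1])
    pts = weighted_points(np.column_stack(feats), weights)
    init = akmc_init(pts, k)
    model = fkcm_iterate(pts, init, m=m, tol=tol, max_iter=max_iter)
    labels = model.memberships.argmax(axis=1).reshape(fused.shape)

    if tumor_cluster is None:
        means = np.array(
            [fused[labels == i].mean() if np.any(labels == i) else -np.inf for i in range(k)]
        )
        tumor_cluster = int(means.argmax())
    mask = labels == tumor_cluster
    return SegmentationResult(
        label_map=labels, tumor_mask=mask, tumor_cluster_id=tumor_cluster, model=model
    )
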