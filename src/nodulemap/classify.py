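"""Two-class labeling of feature maps via Fuzzy C-means, plus AND/OR fusion.

Each feature map (stiffness or CIA) is clustered independently into two
fuzzy clusters.  Standard FCM on 1-D data: memberships and centroids are
updated alternately,

    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)),
    c_j  = sum_i u_ij^m x_i / sum_i u_ij^m,

until the largest membership change falls below a tolerance.  The cluster
with the larger centroid is labeled *tumor* — both features are built to
increase over inclusions — and each point takes the label of its maximal
membership (exact ties resolve to healthy).

The two per-feature label maps are then fused point-wise: AND keeps only
points called tumor by both sensors (fewer false positives), OR keeps
points called tumor by either (fewer false negatives).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FcmParams",
    "ClassificationMap",
    "DegenerateClusteringError",
    "fcm_cluster",
    "fcm_objective",
    "assign_classes",
    "classify_values",
    "fuse_and",
    "fuse_or",
    "save_classification",
    "load_classification",
]


class DegenerateClusteringError(ValueError):
    """Raised when the feature values cannot support two distinct clusters."""


@dataclass(frozen=True)
class FcmParams:
    """Fuzzy C-means hyperparameters (two clusters, fuzzifier m > 1)."""

    n_clusters: int = 2
    m: float = 2.0
    tolerance: float = 1e-5
    max_iterations: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters != 2:
            raise ValueError("only two clusters (tumor/healthy) are supported")
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("invalid convergence parameters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ClassificationMap:
    """Grid-aligned tumor/healthy labels for one detection method.

    ``tumor_membership`` is the fuzzy degree of belonging to the tumor
    cluster; for fused maps it is the corresponding t-norm/t-conorm of the
    input memberships.  ``method`` is one of {"stiffness", "ultrasound",
    "and", "or"}.
    """

    points: np.ndarray
    labels: np.ndarray  # bool, True = tumor
    tumor_membership: np.ndarray
    method: str
    centroids: np.ndarray | None = None
    params: FcmParams | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=bool)
        self.tumor_membership = np.asarray(self.tumor_membership, dtype=float)
        if not (len(self.points) == len(self.labels) == len(self.tumor_membership)):
            raise ValueError("labels must align with the grid")

    @property
    def n_tumor(self) -> int:
        return int(self.labels.sum())


def fcm_cluster(
    values, params: FcmParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run FCM on a 1-D feature array; return (memberships (n, 2), centroids (2,)).

    Memberships are initialized from the seeded RNG, then the standard
    alternating updates run until the maximum absolute membership change
    drops below ``params.tolerance`` or ``params.max_iterations`` is hit.
    Points coincident with a centroid get full membership in that cluster.
    """
    params = params or FcmParams()
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateClusteringError(
            "need at least two distinct feature values to cluster"
        )
    rng = np.random.default_rng(params.seed)
    u = rng.random((x.size, params.n_clusters))
    u /= u.sum(axis=1, keepdims=True)

    exponent = 2.0 / (params.m - 1.0)
    centroids = np.empty(params.n_clusters)
    for _ in range(params.max_iterations):
        um = u**params.m
        centroids = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        d = np.abs(x[:, None] - centroids[None, :])
        # Membership update via d/d_min ratios: the nearest cluster gets
        # weight 1 and farther ones weights in (0, 1], so u_ij = w_ij / sum_k
        # w_ik never overflows even for denormal distances.
        dmin = d.min(axis=1, keepdims=True)
        zero_rows = dmin[:, 0] == 0.0
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            ratios = d / np.where(dmin == 0.0, 1.0, dmin)
            w = ratios**-exponent
            u_new = w / w.sum(axis=1, keepdims=True)
        if zero_rows.any():
            u_new[zero_rows] = 0.0
            u_new[zero_rows, np.argmin(d[zero_rows], axis=1)] = 1.0
        change = float(np.max(np.abs(u_new - u)))
        u = u_new
        if change < params.tolerance:
            break
    return u, centroids


def fcm_objective(values, memberships, centroids, m: float = 2.0) -> float:
    """FCM objective J = sum_ij u_ij^m d_ij^2 (used to compare solutions)."""
    x = np.asarray(values, dtype=float).ravel()
    d2 = (x[:, None] - np.asarray(centroids)[None, :]) ** 2
    return float((np.asarray(memberships) ** m * d2).sum())


def assign_classes(
    memberships: np.ndarray,
    centroids: np.ndarray,
    points,
    method: str,
    params: FcmParams | None = None,
) -> ClassificationMap:
    """Turn FCM output into a tumor/healthy label map.

    The cluster with the larger centroid is the tumor cluster; a point is
    tumor when its tumor membership strictly exceeds 1/2 (ties go healthy).
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids[0] == centroids[1]:
        raise DegenerateClusteringError("equal centroids: degenerate model")
    tumor_cluster = int(np.argmax(centroids))
    tumor_membership = np.asarray(memberships, dtype=float)[:, tumor_cluster]
    labels = tumor_membership > 0.5
    return ClassificationMap(
        points=points,
        labels=labels,
        tumor_membership=tumor_membership,
        method=method,
        centroids=np.sort(centroids),
        params=params,
    )


def classify_values(
    values, points, method: str, params: FcmParams | None = None
) -> ClassificationMap:
    """Cluster one feature map and label it (convenience wrapper)."""
    params = params or FcmParams()
    memberships, centroids = fcm_cluster(values, params)
    return assign_classes(memberships, centroids, points, method, params)


def _check_same_grid(a: ClassificationMap, b: ClassificationMap) -> None:
    if a.points.shape != b.points.shape or not np.allclose(a.points, b.points):
        raise ValueError("classification maps are on different grids")


def fuse_and(a: ClassificationMap, b: ClassificationMap) -> ClassificationMap:
    """Tumor iff tumor in both maps (minimum membership as the fuzzy AND)."""
    _check_same_grid(a, b)
    return ClassificationMap(
        points=a.points,
        labels=a.labels & b.labels,
        tumor_membership=np.minimum(a.tumor_membership, b.tumor_membership),
        method="and",
    )


def fuse_or(a: ClassificationMap, b: ClassificationMap) -> ClassificationMap:
    """Tumor iff tumor in either map (maximum membership as the fuzzy OR)."""
    _check_same_grid(a, b)
    return ClassificationMap(
        points=a.points,
        labels=a.labels | b.labels,
        tumor_membership=np.maximum(a.tumor_membership, b.tumor_membership),
        method="or",
    )


def save_classification(cmap: ClassificationMap, path) -> None:
    """Write a label map as delimited text ({0,1} labels plus memberships)."""
    with open(path, "w") as fh:
        fh.write(f"# method: {cmap.method}\n")
        if cmap.centroids is not None:
            fh.write(f"# centroids: {float(cmap.centroids[0])!r} {float(cmap.centroids[1])!r}\n")
        if cmap.params is not None:
            fh.write(f"# fcm: m={cmap.params.m} tol={cmap.params.tolerance} "
                     f"max_iter={cmap.params.max_iterations} seed={cmap.params.seed}\n")
        fh.write("x_mm\ty_mm\tlabel\ttumor_membership\n")
        for (x, y), lab, mem in zip(cmap.points, cmap.labels, cmap.tumor_membership):
            fh.write(f"{float(x)!r}\t{float(y)!r}\t{int(lab)}\t{float(mem)!r}\n")


def load_classification(path) -> ClassificationMap:
    method = "unknown"
    centroids = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "method:" in line:
                    method = line.split(":", 1)[1].strip()
                elif "centroids:" in line:
                    centroids = np.array(
                        [float(v) for v in line.split(":", 1)[1].split()]
                    )
                continue
            if line.strip() and not line.startswith("x_mm"):
                rows.append([float(v) for v in line.split("\t")])
    arr = np.array(rows)
    return ClassificationMap(
        points=arr[:, :2],
        labels=arr[:, 2] > 0.5,
        tumor_membership=arr[:, 3],
        method=method,
        centroids=centroids,
    )
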