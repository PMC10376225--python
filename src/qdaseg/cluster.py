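"""K-means intensity clustering that seeds the dragonfly swarm.

Four clusters stand in for CSF/background, grey matter, white matter and
tumor.  Lloyd's algorithm on 1D intensities with deterministic seeding (K
evenly spaced quantiles of the pixel distribution), farthest-pixel
empty-cluster repair, and an objective trace that is asserted monotone
non-increasing at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClusterModel", "kmeans", "assign", "identify_tumor_cluster"]


@dataclass
class ClusterModel:
    """K centroids (ascending), per-pixel labels, and the within-cluster
    absolute-distance objective."""

    centroids: np.ndarray
    labels: np.ndarray
    objective: float
    K: int
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.centroids.shape != (self.K,):
            raise ValueError("centroids must be a K-vector")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if np.any(np.diff(self.centroids) < 0):
            raise ValueError("centroids must be in ascending order")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.K
        ):
            raise ValueError("labels must lie in [0, K)")
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


def assign(pixels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid label for each pixel; ties go to the lowest index."""
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    centroids = np.asarray(centroids, dtype=np.float64).ravel()
    if centroids.size == 0:
        raise ValueError("centroids must be nonempty")
    d = np.abs(pixels[:, None] - centroids[None, :])
    return np.argmin(d, axis=1)  # argmin returns the first (lowest) index on ties


def _objective(pixels: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster distance sum (1D Euclidean = absolute distance)."""
    return float(np.sum(np.abs(pixels - centroids[labels])))


def _energy(pixels: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    """Squared-error energy; the quantity Lloyd's steps provably decrease."""
    return float(np.sum((pixels - centroids[labels]) ** 2))


#: above this many distinct values the DP seeding works on an equal-width
#: binning of the intensity axis (exact below, approximate above; Lloyd
#: refines on the raw data either way)
_DP_MAX_LEVELS = 512


def _dp_seed(values: np.ndarray, weights: np.ndarray, K: int) -> np.ndarray:
    """Globally optimal 1D weighted k-means over distinct values.

    Optimal 1D clusters are contiguous in sorted order, so the exact
    solution is a dynamic program over split points (O(K U^2) for U
    levels).  The resulting cluster means are a Lloyd fixed point.
    """
    v = np.asarray(values, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    U = v.size
    W = np.concatenate(([0.0], np.cumsum(w)))
    S = np.concatenate(([0.0], np.cumsum(w * v)))
    Q = np.concatenate(([0.0], np.cumsum(w * v * v)))

    def cost(i: np.ndarray, j: int) -> np.ndarray:
        # weighted SSE of v[i..j] inclusive, vectorized over i
        ww = W[j + 1] - W[i]
        ss = S[j + 1] - S[i]
        qq = Q[j + 1] - Q[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = qq - np.where(ww > 0, ss * ss / ww, 0.0)
        return np.maximum(out, 0.0)

    D = np.full((K, U), np.inf)
    arg = np.zeros((K, U), dtype=np.int64)
    zero = np.array([0])
    D[0] = np.array([cost(zero, j)[0] for j in range(U)])
    for k in range(1, K):
        for j in range(k, U):
            i = np.arange(k, j + 1)  # first index of cluster k
            tot = D[k - 1, i - 1] + cost(i, j)
            m = int(np.argmin(tot))
            D[k, j] = tot[m]
            arg[k, j] = i[m]
    # reconstruct boundaries and means
    seeds = np.empty(K)
    j = U - 1
    for k in range(K - 1, -1, -1):
        i = arg[k, j] if k > 0 else 0
        ww = W[j + 1] - W[i]
        seeds[k] = (S[j + 1] - S[i]) / ww
        j = i - 1
    return seeds


def _seed_centroids(pixels: np.ndarray, K: int) -> np.ndarray:
    values, counts = np.unique(pixels, return_counts=True)
    if values.size > _DP_MAX_LEVELS:
        edges = np.linspace(pixels.min(), pixels.max(), _DP_MAX_LEVELS + 1)
        idx = np.clip(np.digitize(pixels, edges[1:-1]), 0, _DP_MAX_LEVELS - 1)
        counts = np.bincount(idx, minlength=_DP_MAX_LEVELS).astype(np.float64)
        sums = np.bincount(idx, weights=pixels, minlength=_DP_MAX_LEVELS)
        keep = counts > 0
        values = sums[keep] / counts[keep]
        counts = counts[keep]
    return _dp_seed(values, counts.astype(np.float64), K)


def kmeans(
    pixels: np.ndarray,
    K: int = 4,
    tol: float | None = None,
    max_iter: int = 100,
    seed: int | None = None,
) -> ClusterModel:
    """Lloyd iteration on 1D intensities.

    Seeding is deterministic: the exact 1D weighted k-means solution over
    the distinct intensity levels (binned to at most 512 levels), computed
    by dynamic programming; Lloyd then refines on the raw pixels.
    ``seed`` is accepted for interface symmetry but the procedure draws no
    random numbers.  Empty clusters are re-seeded to the pixel farthest
    from its current centroid.  ``tol`` defaults to 1e-4 of the intensity
    dynamic range.
    """
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if np.unique(pixels).size < K:
        raise ValueError(
            f"degenerate input: need >= {K} distinct values, "
            f"got {np.unique(pixels).size}"
        )
    rng_range = float(pixels.max() - pixels.min())
    if tol is None:
        tol = 1e-4 * rng_range if rng_range > 0 else 1e-12

    centroids = np.sort(_seed_centroids(pixels, K))
    for k in range(1, K):
        if centroids[k] <= centroids[k - 1]:
            centroids[k] = np.nextafter(centroids[k - 1], np.inf)

    history: list[float] = []
    labels = assign(pixels, centroids)
    for _ in range(max_iter):
        new_centroids = centroids.copy()
        for k in range(K):
            members = pixels[labels == k]
            if members.size:
                new_centroids[k] = members.mean()
            else:
                # farthest-pixel repair keeps K constant
                far = np.argmax(np.abs(pixels - centroids[labels]))
                new_centroids[k] = pixels[far]
        new_labels = assign(pixels, new_centroids)
        energy = _energy(pixels, new_centroids, new_labels)
        if history and energy > history[-1] + 1e-9 * max(1.0, history[-1]):
            raise AssertionError("k-means energy increased")  # pragma: no cover
        history.append(energy)
        shift = float(np.max(np.abs(new_centroids - centroids)))
        centroids, labels = new_centroids, new_labels
        if shift < tol:
            break

    order = np.argsort(centroids, kind="stable")
    centroids = centroids[order]
    relabel = np.empty(K, dtype=np.int64)
    relabel[order] = np.arange(K)
    labels = relabel[labels]
    obj = _objective(pixels, centroids, labels)
    return ClusterModel(
        centroids=centroids, labels=labels, objective=obj, K=K, history=history
    )


def identify_tumor_cluster(
    cm: ClusterModel,
    strategy: str = "brightest",
    brain_mean: float | None = None,
) -> int:
    """Pick the cluster representing tumor tissue.

    ``"brightest"`` (default): the maximum centroid — matches the
    contrast-enhanced hyperintense appearance.  ``"outlier"``: the centroid
    farthest from the brain-mean intensity (``brain_mean`` defaults to the
    mean centroid).
    """
    if strategy == "brightest":
        return int(np.argmax(cm.centroids))
    if strategy == "outlier":
        ref = float(np.mean(cm.centroids)) if brain_mean is None else float(brain_mean)
        return int(np.argmax(np.abs(cm.centroids - ref)))
    raise ValueError(f"unknown tumor-selection strategy {strategy!r}")
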