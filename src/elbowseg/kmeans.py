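"""Lloyd's k-means on pixel feature vectors.

The clustering objective is the within-cluster sum of squared errors

    SSEWC = sum_i sum_{x in C_i} ||x - mu_i||^2,

minimised by alternating nearest-centroid assignment and centroid-mean
updates.  Its complement, the between-cluster sum of squares

    SSEBC = sum_i |C_i| * ||mu - mu_i||^2

(with mu the grand mean), satisfies SSEWC + SSEBC = total sum of squares
about the grand mean, so minimising one maximises the other.

The estimator :class:`PixelKMeans` follows scikit-learn conventions
(``fit``/``predict``, trailing-underscore fitted attributes); the
module-level functions (:func:`run_kmeans` and the primitive steps) are the
functional surface used by the elbow scan and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .pixels import PixelMatrix

__all__ = [
    "KMeansConfig",
    "KMeansResult",
    "PixelKMeans",
    "init_centroids",
    "assign_points",
    "update_centroids",
    "sse_within",
    "sse_between",
    "total_ss",
    "run_kmeans",
]

INIT_METHODS = ("kmeanspp", "random_points")


# ----------------------------------------------------------------------
# configuration / result records
# ----------------------------------------------------------------------
@dataclass
class KMeansConfig:
    """Parameters of one k-means run (k restarts of Lloyd's algorithm)."""

    k: int
    init_method: str = "kmeanspp"
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.init_method not in INIT_METHODS:
            raise ValueError(
                f"unknown init_method {self.init_method!r}; choose from {INIT_METHODS}"
            )
        if self.n_init < 1:
            raise ValueError(f"n_init must be >= 1, got {self.n_init}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol < 0:
            raise ValueError(f"tol must be >= 0, got {self.tol}")


@dataclass
class KMeansResult:
    """Fitted clustering for one value of k.

    ``sse_history`` records SSEWC after every assign/update pair of the
    winning restart; it is non-increasing by construction of Lloyd's
    algorithm and is asserted on in the invariant tests.
    """

    centroids: np.ndarray          # (k, D)
    labels: np.ndarray             # (N,) ints in [0, k)
    sse_within: float
    sse_between: float
    n_iter: int
    converged: bool
    seed_used: int
    cluster_sizes: np.ndarray      # (k,) counts, all >= 1
    sse_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------
def _as_features(data) -> np.ndarray:
    if isinstance(data, PixelMatrix):
        return data.features
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected 2-D data, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data contains non-finite values")
    return x


def init_centroids(data, k: int, method: str = "kmeanspp", seed: int = 0) -> np.ndarray:
    """Draw k initial centroids from the data rows.

    ``random_points`` samples k distinct rows uniformly;  ``kmeanspp`` uses
    the standard D^2-weighted sequential scheme (each next centroid drawn
    with probability proportional to squared distance from the nearest
    centroid chosen so far).  Deterministic given (data, k, method, seed).
    """
    x = _as_features(data)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and the number of points n={n}")
    rng = np.random.default_rng(seed)
    if method == "random_points":
        idx = rng.choice(n, size=k, replace=False)
        return x[idx].copy()
    if method != "kmeanspp":
        raise ValueError(
            f"unknown init method {method!r}; choose from {INIT_METHODS}"
        )
    centroids = np.empty((k, x.shape[1]), dtype=np.float64)
    centroids[0] = x[rng.integers(n)]
    d2 = cdist(x, centroids[:1], "sqeuclidean")[:, 0]
    for i in range(1, k):
        total = d2.sum()
        if total <= 0.0:
            # all points coincide with an existing centroid: fall back to uniform
            centroids[i] = x[rng.integers(n)]
        else:
            centroids[i] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, cdist(x, centroids[i : i + 1], "sqeuclidean")[:, 0])
    return centroids


def assign_points(data, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels (squared Euclidean; ties to the lowest index)."""
    x = _as_features(data)
    c = np.asarray(centroids, dtype=np.float64)
    if c.ndim != 2 or c.shape[1] != x.shape[1]:
        raise ValueError(
            f"centroid dimensionality {c.shape} does not match data "
            f"dimensionality {x.shape[1]}"
        )
    if not np.all(np.isfinite(c)):
        raise ValueError("centroids contain non-finite values")
    # cdist evaluates (x - c)^2 termwise, so exactly equidistant points get
    # exactly equal distances and argmin's first-match rule is the tie-break.
    return np.argmin(cdist(x, c, "sqeuclidean"), axis=1)


def update_centroids(data, labels: np.ndarray, k: int):
    """Per-cluster means; returns ``(centroids, empty_cluster_indices)``.

    Rows of empty clusters are NaN-free copies of nothing meaningful (zeros);
    callers must repair them before use — :class:`PixelKMeans` reseeds each
    empty cluster on the farthest point from its current centroid.
    """
    x = _as_features(data)
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels length does not match number of points")
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    d = x.shape[1]
    centroids = np.zeros((k, d), dtype=np.float64)
    counts = np.bincount(labels, minlength=k)
    np.add.at(centroids, labels, x)
    empty = np.flatnonzero(counts == 0)
    nonzero = counts > 0
    centroids[nonzero] /= counts[nonzero, None]
    return centroids, list(empty)


def sse_within(data, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Within-cluster sum of squared errors: sum_i sum_{x in C_i} ||x - mu_i||^2."""
    x = _as_features(data)
    c = np.asarray(centroids, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels length does not match number of points")
    if c.ndim != 2 or c.shape[1] != x.shape[1]:
        raise ValueError("centroid shape does not match data")
    diff = x - c[labels]
    return float(np.einsum("ij,ij->", diff, diff))


def sse_between(data, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Between-cluster sum of squares: sum_i |C_i| * ||mu - mu_i||^2."""
    x = _as_features(data)
    c = np.asarray(centroids, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels length does not match number of points")
    if c.ndim != 2 or c.shape[1] != x.shape[1]:
        raise ValueError("centroid shape does not match data")
    counts = np.bincount(labels, minlength=c.shape[0]).astype(np.float64)
    grand = x.mean(axis=0)
    diff = grand[None, :] - c
    return float(np.sum(counts * np.einsum("ij,ij->i", diff, diff)))


def total_ss(data) -> float:
    """Total sum of squared deviations about the grand mean."""
    x = _as_features(data)
    diff = x - x.mean(axis=0)
    return float(np.einsum("ij,ij->", diff, diff))


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------
class PixelKMeans(ClusterMixin, BaseEstimator):
    """Lloyd's k-means clusterer with restarts and empty-cluster repair.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    init : {"kmeanspp", "random_points"}
        Initial-centroid scheme.  k-means++ is the default: plain Lloyd from
        uniformly drawn pixels frequently stalls in poor local minima on
        images, which is the classic weakness of the bare algorithm.
    n_init : int
        Independent restarts; the restart with the lowest within-cluster SSE
        wins.  Restart r uses seed ``random_state + r``.
    max_iter : int
        Iteration cap per restart.
    tol : float
        Relative SSEWC-change convergence threshold (label stability is also
        checked; whichever triggers first stops the restart).
    random_state : int
        Base seed; every source of randomness flows from it.
    warm_start_centroids : ndarray, optional
        Extra restart initialised at these exact centroids (used by the
        elbow scan to chain solutions across k and keep the SSE-vs-k curve
        monotone).

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, D)
    labels_ : ndarray of shape (N,)
    sse_within_, sse_between_ : float
        The two sum-of-squares objectives; ``inertia_`` aliases
        ``sse_within_`` for scikit-learn compatibility.
    cluster_sizes_ : ndarray of shape (k,), all entries >= 1
    n_iter_ : int
    converged_ : bool
    sse_history_ : ndarray
        SSEWC after each assign/update pair of the winning restart.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        init: str = "kmeanspp",
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int = 0,
        warm_start_centroids: np.ndarray | None = None,
    ):
        self.n_clusters = n_clusters
        self.init = init
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.warm_start_centroids = warm_start_centroids

    # -- single restart of Lloyd's algorithm ---------------------------
    def _lloyd(self, x: np.ndarray, centroids: np.ndarray):
        k = self.n_clusters
        prev_labels = None
        prev_sse = np.inf
        history = []
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d2 = cdist(x, centroids, "sqeuclidean")
            labels = np.argmin(d2, axis=1)
            centroids, empty = update_centroids(x, labels, k)
            if empty:
                # reseed each empty cluster on the point farthest from its
                # current centroid, excluding points already taken
                point_d2 = cdist(x, centroids, "sqeuclidean")[
                    np.arange(x.shape[0]), labels
                ]
                taken: set[int] = set()
                for j in empty:
                    order = np.argsort(point_d2)[::-1]
                    far = next(int(i) for i in order if int(i) not in taken)
                    taken.add(far)
                    centroids[j] = x[far]
                    point_d2[far] = -1.0
            sse = sse_within(x, labels, centroids)
            history.append(sse)
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                converged = True
                break
            if prev_sse < np.inf:
                denom = prev_sse if prev_sse > 0 else 1.0
                if (prev_sse - sse) / denom < self.tol:
                    converged = True
                    break
            prev_labels = labels
            prev_sse = sse
        return labels, centroids, sse, n_iter, converged, np.asarray(history)

    def fit(self, X, y=None) -> "PixelKMeans":
        x = _as_features(X)
        n = x.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(
                f"n_clusters={self.n_clusters} must be between 1 and n={n}"
            )
        KMeansConfig(  # validates the numeric parameters
            k=self.n_clusters,
            init_method=self.init,
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )

        starts: list[tuple[int, np.ndarray]] = []
        for r in range(self.n_init):
            seed = self.random_state + r
            starts.append((seed, init_centroids(x, self.n_clusters, self.init, seed)))
        if self.warm_start_centroids is not None:
            w = np.asarray(self.warm_start_centroids, dtype=np.float64)
            if w.shape != (self.n_clusters, x.shape[1]):
                raise ValueError(
                    f"warm_start_centroids shape {w.shape} does not match "
                    f"({self.n_clusters}, {x.shape[1]})"
                )
            starts.append((self.random_state, w))

        best = None
        for seed, c0 in starts:
            out = self._lloyd(x, c0.copy())
            if best is None or out[2] < best[1][2]:
                best = (seed, out)
        seed_used, (labels, centroids, sse, n_iter, converged, history) = best

        self.labels_ = labels
        self.cluster_centers_ = centroids
        self.sse_within_ = sse
        self.sse_between_ = sse_between(x, labels, centroids)
        self.inertia_ = sse
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.seed_used_ = seed_used
        self.cluster_sizes_ = np.bincount(labels, minlength=self.n_clusters)
        self.sse_history_ = history
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return assign_points(X, self.cluster_centers_)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def result_(self) -> KMeansResult:
        """Bundle the fitted attributes as a :class:`KMeansResult` record."""
        return KMeansResult(
            centroids=self.cluster_centers_,
            labels=self.labels_,
            sse_within=self.sse_within_,
            sse_between=self.sse_between_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            seed_used=self.seed_used_,
            cluster_sizes=self.cluster_sizes_,
            sse_history=self.sse_history_,
        )


def run_kmeans(data, config: KMeansConfig) -> KMeansResult:
    """Best-of-``n_init`` k-means (lowest SSEWC wins); see :class:`PixelKMeans`."""
    est = PixelKMeans(
        n_clusters=config.k,
        init=config.init_method,
        n_init=config.n_init,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed,
    )
    return est.fit(data).result_()
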