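"""SSE-vs-k curves and elbow (knee) detection for choosing the cluster count.

As k grows, the within-cluster sum of squares (SSEWC) falls steeply while k
is below the true number of color populations and flattens out beyond it;
the "elbow" — the point of highest curvature of the curve — marks the best
k.

Because the SSE of a pixel-color curve typically spans orders of magnitude
(the k=1 to k=2 drop dwarfs everything else), curvature is scored on the
log of the SSE, min-max normalised to [0, 1] in both axes.  On the log
scale the elbow is the change in geometric decay rate, which is exactly
what separates "still splitting real color populations" from "shaving
noise"; scoring the raw curve instead reliably mistakes the first big
split (k=2) for the elbow.  Three detectors are offered:

``kneedle`` (default)
    the Kneedle difference curve: flip the normalised curve to increasing
    concave form and score its vertical excess over the diagonal.
``second_difference``
    score(k) = s(k-1) - 2 s(k) + s(k+1); the discrete second derivative.
``discrete_curvature``
    Menger curvature (inverse circumradius) of consecutive curve triples.

All three score only interior k (curvature is undefined at the endpoints)
and break ties toward smaller k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kmeans import KMeansConfig, KMeansResult, PixelKMeans, assign_points, _as_features
from sklearn.base import BaseEstimator, ClusterMixin
from scipy.spatial.distance import cdist

__all__ = [
    "SSECurve",
    "ElbowSelection",
    "ElbowKMeans",
    "compute_sse_curve",
    "select_k_elbow",
    "plot_sse_curve",
]

ELBOW_METHODS = ("kneedle", "second_difference", "discrete_curvature")
DEFAULT_ELBOW_METHOD = "kneedle"


@dataclass
class SSECurve:
    """SSEWC as a function of k, with the fitted model kept for each k."""

    k_values: np.ndarray                       # strictly increasing ints
    sse_values: np.ndarray                     # matching non-negative reals
    per_k_results: dict[int, KMeansResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.sse_values = np.asarray(self.sse_values, dtype=np.float64)
        if self.k_values.shape != self.sse_values.shape:
            raise ValueError("k_values and sse_values must have equal length")
        if len(self.k_values) < 3:
            raise ValueError("need at least three curve points to locate an elbow")
        if np.any(np.diff(self.k_values) <= 0):
            raise ValueError("k_values must be strictly increasing")
        if np.any(self.sse_values < 0):
            raise ValueError("sse_values must be non-negative")


@dataclass
class ElbowSelection:
    """Chosen k plus per-candidate elbow scores (higher = more elbow-like)."""

    chosen_k: int
    method: str
    scores: np.ndarray          # aligned with curve.k_values; NaN at endpoints
    curve: SSECurve
    low_confidence: bool = False
    message: str = ""


# ----------------------------------------------------------------------
def compute_sse_curve(data, k_min: int, k_max: int, config: KMeansConfig | None = None) -> SSECurve:
    """Best-of-restarts SSEWC for every k in [k_min, k_max].

    For k > k_min one extra warm-started restart is seeded with the previous
    k's centroids plus the point farthest from its centroid; splitting off
    that point can only lower the objective, which keeps the returned curve
    non-increasing even when the random restarts are unlucky.
    """
    x = _as_features(data)
    n = x.shape[0]
    if not (1 <= k_min < k_max <= n):
        raise ValueError(
            f"need 1 <= k_min < k_max <= n, got k_min={k_min}, k_max={k_max}, n={n}"
        )
    if k_max - k_min < 2:
        raise ValueError(
            f"need at least three k values (k_max - k_min >= 2), got "
            f"k_min={k_min}, k_max={k_max}"
        )
    if config is None:
        config = KMeansConfig(k=k_min)

    k_values = np.arange(k_min, k_max + 1)
    sse_values = np.empty(len(k_values))
    per_k: dict[int, KMeansResult] = {}
    prev: KMeansResult | None = None
    for i, k in enumerate(k_values):
        warm = None
        if prev is not None:
            d2 = cdist(x, prev.centroids, "sqeuclidean")[
                np.arange(n), prev.labels
            ]
            far = int(np.argmax(d2))
            warm = np.vstack([prev.centroids, x[far]])
        est = PixelKMeans(
            n_clusters=int(k),
            init=config.init_method,
            n_init=config.n_init,
            max_iter=config.max_iter,
            tol=config.tol,
            random_state=config.seed,
            warm_start_centroids=warm,
        )
        res = est.fit(x).result_()
        per_k[int(k)] = res
        sse_values[i] = res.sse_within
        prev = res
    return SSECurve(k_values=k_values, sse_values=sse_values, per_k_results=per_k)


def _normalize_curve(curve: SSECurve):
    """Log-transform the SSE, then min-max normalise both axes to [0, 1].

    Exact zeros (noise-free data at k >= k_true) are floored at 1e-15 of
    the curve maximum before the log.  A flat curve maps y to all-zero and
    is flagged degenerate.
    """
    xk = curve.k_values.astype(np.float64)
    y = curve.sse_values
    xn = (xk - xk[0]) / (xk[-1] - xk[0])
    floor = max(float(y.max()), 1.0) * 1e-15
    ylog = np.log(np.maximum(y, floor))
    span = ylog.max() - ylog.min()
    if span <= 0:
        return xn, np.zeros_like(y), True
    return xn, (ylog - ylog.min()) / span, False


def select_k_elbow(curve: SSECurve, method: str = DEFAULT_ELBOW_METHOD) -> ElbowSelection:
    """Pick the k at the elbow of an SSE-vs-k curve.

    Non-monotone curves (SSE rising with k by more than 1e-9 relative — the
    signature of under-restarted upstream runs) are repaired to their
    running minimum with a warning before scoring.  Endpoints are never
    selectable; a curve with no elbow (all scores ~0, e.g. an exactly linear
    curve) returns the smallest interior k flagged low-confidence.
    """
    if method not in ELBOW_METHODS:
        raise ValueError(f"unknown elbow method {method!r}; choose from {ELBOW_METHODS}")
    y = curve.sse_values
    rises = np.diff(y)
    scale = max(y.max(), 1.0)
    if np.any(rises > 1e-9 * scale):
        warnings.warn(
            "SSE curve increases with k (under-restarted k-means upstream?); "
            "repairing to the running minimum",
            stacklevel=2,
        )
        curve = SSECurve(
            k_values=curve.k_values,
            sse_values=np.minimum.accumulate(y),
            per_k_results=curve.per_k_results,
        )

    xn, yn, flat = _normalize_curve(curve)
    m = len(xn)
    scores = np.full(m, np.nan)
    if method == "second_difference":
        for i in range(1, m - 1):
            scores[i] = yn[i - 1] - 2.0 * yn[i] + yn[i + 1]
    elif method == "kneedle":
        # flip the decreasing curve to increasing-concave, then score the
        # difference curve (vertical excess over the diagonal)
        diff = (1.0 - yn) - xn
        scores[1:-1] = diff[1:-1]
    else:  # discrete_curvature: Menger curvature of consecutive triples,
        # signed by convexity — a concave bend is not an elbow
        for i in range(1, m - 1):
            a = np.array([xn[i - 1], yn[i - 1]])
            b = np.array([xn[i], yn[i]])
            c = np.array([xn[i + 1], yn[i + 1]])
            area2 = abs(
                (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
            )
            denom = (
                np.linalg.norm(b - a) * np.linalg.norm(c - b) * np.linalg.norm(c - a)
            )
            curv = 0.0 if denom == 0 else 2.0 * area2 / denom
            convexity = yn[i - 1] - 2.0 * yn[i] + yn[i + 1]
            scores[i] = curv if convexity > 0 else -curv

    interior = scores[1:-1]
    best_rel = int(np.nanargmax(interior))  # argmax takes the first = smallest k
    chosen_k = int(curve.k_values[1 + best_rel])
    low_conf = flat or bool(np.nanmax(interior) <= 1e-12)
    msg = ""
    if low_conf:
        msg = (
            "no discernible elbow (flat or linear SSE curve); "
            "returned the smallest interior k"
        )
        chosen_k = int(curve.k_values[1])
    return ElbowSelection(
        chosen_k=chosen_k,
        method=method,
        scores=scores,
        curve=curve,
        low_confidence=low_conf,
        message=msg,
    )


def plot_sse_curve(curve: SSECurve, selection: ElbowSelection | None = None, path=None):
    """SSEWC-vs-k plot with the chosen k marked; writes PNG/SVG if path given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.k_values, curve.sse_values, "o-", color="tab:blue")
    if selection is not None:
        k = selection.chosen_k
        s = curve.sse_values[np.searchsorted(curve.k_values, k)]
        ax.axvline(k, color="tab:red", ls="--", lw=1)
        ax.plot([k], [s], "o", color="tab:red", ms=8)
        ax.annotate(f"elbow k={k}", (k, s), textcoords="offset points", xytext=(8, 8))
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("within-cluster SSE")
    ax.set_xticks(curve.k_values)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ----------------------------------------------------------------------
class ElbowKMeans(ClusterMixin, BaseEstimator):
    """K-means with the cluster count chosen automatically at the elbow.

    ``fit`` scans k over [k_min, k_max], selects the elbow of the SSEWC
    curve with the chosen detector, and exposes the clustering at that k.

    Attributes
    ----------
    chosen_k_ : int
    curve_ : SSECurve
    selection_ : ElbowSelection
    cluster_centers_, labels_, sse_within_, sse_between_, inertia_,
    cluster_sizes_ : the fitted model at ``chosen_k_``.
    """

    def __init__(
        self,
        k_min: int = 1,
        k_max: int = 10,
        method: str = DEFAULT_ELBOW_METHOD,
        init: str = "kmeanspp",
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.method = method
        self.init = init
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None) -> "ElbowKMeans":
        config = KMeansConfig(
            k=max(self.k_min, 1),
            init_method=self.init,
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )
        self.curve_ = compute_sse_curve(X, self.k_min, self.k_max, config)
        self.selection_ = select_k_elbow(self.curve_, self.method)
        self.chosen_k_ = self.selection_.chosen_k
        res = self.curve_.per_k_results[self.chosen_k_]
        self.cluster_centers_ = res.centroids
        self.labels_ = res.labels
        self.sse_within_ = res.sse_within
        self.sse_between_ = res.sse_between
        self.inertia_ = res.sse_within
        self.cluster_sizes_ = res.cluster_sizes
        self.n_features_in_ = res.centroids.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return assign_points(X, self.cluster_centers_)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def result_(self) -> KMeansResult:
        return self.curve_.per_k_results[self.chosen_k_]
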