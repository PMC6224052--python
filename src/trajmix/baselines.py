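"""Partition-based baselines and internal cluster-validity indexes.

PAM (k-medoids by BUILD + SWAP), CLARA (best-of-samples PAM) and fuzzy
C-means operate on fixed-length vectors; variable-length count series are
right-padded with zeros to the maximum length and compared with Euclidean
distance.  That vectorization is an assumption of this benchmark, not a
property of the trajectories -- the metric is pluggable via the ``metric``
argument of :func:`pad_series`.

Silhouette values come from scikit-learn; the Dunn index and classical
(Torgerson) multidimensional scaling are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

__all__ = [
    "VectorizedSeries",
    "pad_series",
    "pam",
    "clara",
    "fcm",
    "silhouette_summary",
    "dunn",
    "mds_2d",
    "validation_report",
]


@dataclass(frozen=True)
class VectorizedSeries:
    """Zero-padded series matrix plus its pairwise distance matrix."""

    claim_ids: tuple[str, ...]
    vectors: np.ndarray  # (n, L)
    distances: np.ndarray  # (n, n) symmetric, zero diagonal


def pad_series(series_set, metric: str = "euclidean") -> VectorizedSeries:
    """Right-pad series with zeros to a common length; compute distances."""
    counts = [np.asarray(getattr(s, "counts", s), dtype=float) for s in series_set]
    if not counts:
        raise ValueError("empty series set")
    ids = tuple(
        str(getattr(s, "claim_id", i)) for i, s in enumerate(series_set)
    )
    L = max(len(c) for c in counts)
    X = np.zeros((len(counts), L))
    for i, c in enumerate(counts):
        X[i, : len(c)] = c
    D = squareform(pdist(X, metric=metric))
    return VectorizedSeries(claim_ids=ids, vectors=X, distances=D)


# ---------------------------------------------------------------------------
# PAM / CLARA


def _pam_cost(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam(D: np.ndarray, n_clusters: int, seed: int | None = None, max_iter: int = 200):
    """Partitioning around medoids: greedy BUILD then steepest-descent SWAP.

    Deterministic given the distance matrix (the seed only breaks exact cost
    ties among candidate swaps, which are resolved toward the lowest index).
    Returns (labels, medoid indices); the total distance to the nearest
    medoid is non-increasing over swap iterations.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError("need 1 <= n_clusters <= n")
    # BUILD: first medoid minimizes total distance; then greedily add the
    # point yielding the largest cost reduction.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < n_clusters:
        cur = D[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))

    for _ in range(max_iter):
        cost = _pam_cost(D, medoids)
        best_delta, best_swap = 0.0, None
        dist_to_med = D[:, medoids]
        nearest = np.argmin(dist_to_med, axis=1)
        for j, m in enumerate(medoids):
            # distance to nearest medoid excluding m
            other = np.delete(medoids, j)
            d_wo = D[:, other].min(axis=1) if len(other) else np.full(n, np.inf)
            cand = np.setdiff1d(np.arange(n), medoids)
            if cand.size == 0:
                continue
            new_costs = np.minimum(d_wo[:, None], D[:, cand]).sum(axis=0)
            k = int(np.argmin(new_costs))
            delta = new_costs[k] - cost
            if delta < best_delta - 1e-12:
                best_delta, best_swap = delta, (j, cand[k])
        if best_swap is None:
            break
        j, h = best_swap
        medoids[j] = h
        medoids = np.array(sorted(medoids))
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids


def clara(
    D: np.ndarray,
    n_clusters: int,
    sample_size: int = 50,
    n_samples: int = 5,
    seed: int | None = None,
):
    """PAM on random subsamples, keeping the best clustering by full cost.

    When the sample covers the whole dataset the result reduces to PAM.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    sample_size = min(sample_size, n)
    best = None
    for _ in range(max(n_samples, 1)):
        if sample_size >= n:
            idx = np.arange(n)
        else:
            idx = np.sort(rng.choice(n, size=sample_size, replace=False))
        _, med_local = pam(D[np.ix_(idx, idx)], n_clusters)
        medoids = idx[med_local]
        cost = _pam_cost(D, medoids)
        if best is None or cost < best[0]:
            best = (cost, medoids)
    medoids = best[1]
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids


# ---------------------------------------------------------------------------
# Fuzzy C-means


def fcm(
    X: np.ndarray,
    n_clusters: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
):
    """Fuzzy C-means by alternating optimization.

    Returns (membership matrix U of shape (n, M), centers).  The objective
    sum_i sum_m U[i,m]^q ||x_i - c_m||^2 is non-increasing across iterations.
    Points coincident with a center get membership 1 for that cluster.
    """
    X = np.asarray(X, dtype=float)
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    q = fuzzifier

    def memberships(centers):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (d2[:, :, None] / d2[:, None, :]) ** (1.0 / (q - 1.0))
            U = 1.0 / ratio.sum(axis=2)
        coincident = zero.any(axis=1)
        U[coincident] = zero[coincident] / zero[coincident].sum(
            axis=1, keepdims=True
        )
        return U, d2

    # seed centers with mutually distant data points (a near-uniform
    # membership start is a saddle of the FCM objective and stalls there)
    first = int(rng.integers(n))
    chosen = [first]
    for _ in range(n_clusters - 1):
        d = np.min(
            ((X[:, None, :] - X[chosen][None]) ** 2).sum(axis=2), axis=1
        )
        chosen.append(int(np.argmax(d)))
    centers = X[chosen].astype(float)
    prev_obj = np.inf
    for _ in range(max_iter):
        U, d2 = memberships(centers)
        W = U**q
        obj = float((W * d2).sum())
        centers = (W.T @ X) / np.maximum(W.sum(axis=0)[:, None], 1e-300)
        if prev_obj - obj <= tol * max(abs(prev_obj), 1.0):
            break
        prev_obj = obj
    U, _ = memberships(centers)
    return U, centers


# ---------------------------------------------------------------------------
# Validity indexes


def silhouette_summary(D: np.ndarray, labels) -> dict[str, float]:
    """Six-number summary (min, Q1, median, mean, Q3, max) of silhouettes.

    Uses the precomputed distance matrix; singleton clusters score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two clusters")
    s = silhouette_samples(np.asarray(D, dtype=float), labels, metric="precomputed")
    return {
        "min": float(s.min()),
        "q1": float(np.percentile(s, 25)),
        "median": float(np.median(s)),
        "mean": float(s.mean()),
        "q3": float(np.percentile(s, 75)),
        "max": float(s.max()),
    }


def dunn(D: np.ndarray, labels) -> float:
    """Dunn index: min inter-cluster distance / max intra-cluster diameter.

    Returns ``inf`` when every cluster has zero diameter.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    inter = np.inf
    intra = 0.0
    for i, a in enumerate(uniq):
        ia = labels == a
        intra = max(intra, float(D[np.ix_(ia, ia)].max()))
        for b in uniq[i + 1 :]:
            inter = min(inter, float(D[np.ix_(ia, labels == b)].min()))
    return np.inf if intra == 0 else inter / intra


def mds_2d(D: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) MDS to 2-D.

    Double-centers the squared distances and projects on the top-2
    eigenvectors scaled by the square root of their eigenvalues.  The sign of
    each axis is fixed so its largest-magnitude coordinate is positive.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1][:2]
    coords = np.zeros((n, 2))
    scale = max(float(vals.max()), 0.0)
    for k, idx in enumerate(order):
        lam = max(vals[idx], 0.0)
        if lam <= scale * 1e-12:
            lam = 0.0  # numerically-zero eigenvalue: axis carries no variance
        v = vecs[:, idx]
        if np.abs(v).max() > 0 and v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, k] = np.sqrt(lam) * v
    return coords


def validation_report(D: np.ndarray, labels_by_method: dict[str, np.ndarray]):
    """Table-2-style comparison: sizes, silhouette summary and Dunn per method."""
    import pandas as pd

    rows = []
    for method, labels in labels_by_method.items():
        labels = np.asarray(labels)
        sizes = {
            f"size_{k + 1}": int((labels == u).sum())
            for k, u in enumerate(np.unique(labels))
        }
        sil = silhouette_summary(D, labels)
        rows.append(
            dict(
                method=method,
                **sizes,
                **{f"silhouette_{k}": v for k, v in sil.items()},
                dunn=dunn(D, labels),
            )
        )
    return pd.DataFrame(rows)
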