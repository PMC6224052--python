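"""Independent brute-force oracles used across the test suite.

Everything here enumerates explicitly (all state paths, all pairs, all medoid
subsets) and is deliberately written without reference to the package's own
recursions, so that agreement between the two routes is meaningful.
"""

from itertools import combinations, product

import numpy as np


def enumerate_paths(x, pi, A, B):
    """All state paths with their joint probabilities p(x, y).

    Returns (paths list, joint probabilities array).  Exponential in T; only
    for tiny instances.
    """
    x = np.asarray(x, dtype=int)
    N = len(pi)
    paths = list(product(range(N), repeat=len(x)))
    probs = np.empty(len(paths))
    for i, y in enumerate(paths):
        p = pi[y[0]] * B[y[0], x[0]]
        for t in range(1, len(x)):
            p *= A[y[t - 1], y[t]] * B[y[t], x[t]]
        probs[i] = p
    return paths, probs


def brute_log_likelihood(x, pi, A, B):
    _, probs = enumerate_paths(x, pi, A, B)
    total = probs.sum()
    return np.log(total) if total > 0 else -np.inf


def brute_posteriors(x, pi, A, B):
    """(gamma, xi) posteriors from exhaustive path enumeration."""
    x = np.asarray(x, dtype=int)
    T, N = len(x), len(pi)
    paths, probs = enumerate_paths(x, pi, A, B)
    total = probs.sum()
    gamma = np.zeros((T, N))
    xi = np.zeros((max(T - 1, 0), N, N))
    for y, p in zip(paths, probs):
        for t in range(T):
            gamma[t, y[t]] += p
        for t in range(T - 1):
            xi[t, y[t], y[t + 1]] += p
    return gamma / total, xi / total


def brute_viterbi(x, pi, A, B):
    """(best log joint, best path) with ties broken like the package:
    among equal-probability paths, the package's backtrack prefers the lower
    state index, which corresponds to the lexicographically smallest path
    among maximizers when scanned from the end; we simply return the max
    probability (path comparisons in tests only assert probability equality
    unless the maximizer is unique)."""
    paths, probs = enumerate_paths(x, pi, A, B)
    i = int(np.argmax(probs))
    with np.errstate(divide="ignore"):
        return float(np.log(probs[i])), list(paths[i])


def random_hmm(rng, N, K):
    """Random stochastic parameter triple (pi, A, B)."""
    pi = rng.dirichlet(np.ones(N) * 1.5)
    A = rng.dirichlet(np.ones(N) * 1.5, size=N)
    B = rng.dirichlet(np.ones(K) * 1.5, size=N)
    return pi, A, B


def brute_silhouette(D, labels):
    """Per-point silhouette s(i) from the definition; singleton clusters -> 0."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(
            D[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return s


def brute_dunn(D, labels):
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    inter = min(
        D[np.ix_(labels == a, labels == b)].min()
        for a in uniq
        for b in uniq
        if a < b
    )
    intra = max(
        D[np.ix_(labels == a, labels == a)].max() for a in uniq
    )
    return np.inf if intra == 0 else inter / intra


def brute_pam_cost(D, medoids):
    return np.asarray(D)[:, list(medoids)].min(axis=1).sum()


def brute_best_medoids(D, M):
    """Exhaustive search over all medoid subsets of size M."""
    n = len(D)
    best, best_cost = None, np.inf
    for med in combinations(range(n), M):
        c = brute_pam_cost(D, med)
        if c < best_cost:
            best, best_cost = med, c
    return best, best_cost
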