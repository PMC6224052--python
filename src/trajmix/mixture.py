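"""Mixture of hidden Markov models fitted by EM over whole trajectories.

The mixture indicator ``z`` clusters entire sequences: the joint model is

    p(x_{1:T}, y_{1:T}, z) = w[z] * pi_z[y_1] * prod A_z * prod B_z

Fitting alternates an E step (per-sequence cluster responsibilities plus
responsibility-weighted state posteriors) with closed-form M-step updates of
the mixture weights and every component's (pi, A, B).

Two numerical routes coexist on purpose: the public per-sequence log-space
recursions in :mod:`trajmix.hmm`, and a scaled linear-space implementation
batched over sequences (padded to a common length and masked) that makes EM
fast enough for hundreds of restarts.  The two are cross-checked in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .hmm import HMMParams

__all__ = [
    "MHMMParams",
    "Assignment",
    "FitResult",
    "SuffStats",
    "e_step",
    "m_step",
    "fit_em",
    "assign_clusters",
    "total_log_likelihood",
]

EMISSION_FLOOR = 1e-10


@dataclass(frozen=True)
class MHMMParams:
    """Mixture weights plus M component HMMs sharing N states and support K."""

    weights: np.ndarray
    components: tuple[HMMParams, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) != self.weights.shape[0]:
            raise ValueError("weights and components length mismatch")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be a probability vector")
        ns = {c.n_states for c in self.components}
        ks = {c.support_size for c in self.components}
        if len(ns) != 1 or len(ks) != 1:
            raise ValueError("all components must share N and K")

    @property
    def n_clusters(self) -> int:
        return len(self.components)

    @property
    def n_states(self) -> int:
        return self.components[0].n_states

    @property
    def support_size(self) -> int:
        return self.components[0].support_size

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "components": [c.to_dict() for c in self.components],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MHMMParams":
        return cls(
            weights=np.array(d["weights"], dtype=float),
            components=tuple(HMMParams.from_dict(c) for c in d["components"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MHMMParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class Assignment:
    """Posterior cluster membership of one trajectory."""

    claim_id: str
    posterior: np.ndarray
    hard_label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "posterior", np.asarray(self.posterior, dtype=float))
        if not np.isclose(self.posterior.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior must sum to 1")
        if self.hard_label != int(np.argmax(self.posterior)):
            raise ValueError("hard_label must be the argmax of the posterior")


@dataclass(frozen=True)
class SuffStats:
    """Expected sufficient statistics accumulated over all sequences."""

    resp_sum: np.ndarray  # (M,)   sum of cluster responsibilities
    initial: np.ndarray  # (M, N) responsibility-weighted gamma at t=1
    transition: np.ndarray  # (M, N, N) responsibility-weighted xi sums
    emission: np.ndarray  # (M, N, K) responsibility-weighted emission counts
    loglik: float


@dataclass(frozen=True)
class FitResult:
    params: MHMMParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int | None = None
    restart: int | None = None
    assignments: tuple[Assignment, ...] = field(default=(), repr=False)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


# ---------------------------------------------------------------------------
# Batched (padded + masked) scaled-linear forward-backward


def _pack(series_counts: Sequence[Sequence[int]], K: int):
    """Pad sequences to a common length; returns (X, mask, lengths)."""
    lengths = np.array([len(c) for c in series_counts], dtype=int)
    if np.any(lengths < 1):
        raise ValueError("empty sequence")
    n, tmax = len(series_counts), int(lengths.max())
    X = np.zeros((n, tmax), dtype=int)
    for i, c in enumerate(series_counts):
        ci = np.asarray(c, dtype=int)
        if np.any(ci < 0) or np.any(ci >= K):
            raise ValueError(
                f"sequence {i} has counts outside the support {{0..{K - 1}}}"
            )
        X[i, : lengths[i]] = ci
    mask = np.arange(tmax)[None, :] < lengths[:, None]
    return X, mask, lengths


def _component_posteriors(X, mask, lengths, hmm: HMMParams):
    """Scaled forward-backward for one component over all padded sequences.

    Returns (loglik (n,), gamma (n,T,N), xi_sum (n,N,N)).
    """
    n, tmax = X.shape
    N = hmm.n_states
    Bobs = hmm.emission.T[X]  # (n, T, N)
    A = hmm.transition

    alpha = np.empty((n, tmax, N))
    c = np.ones((n, tmax))
    dead = np.zeros(n, dtype=bool)
    a = hmm.initial[None, :] * Bobs[:, 0]
    c0 = a.sum(axis=1)
    dead |= c0 <= 0
    c[:, 0] = np.where(c0 > 0, c0, 1.0)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, tmax):
        a = (alpha[:, t - 1] @ A) * Bobs[:, t]
        ct = a.sum(axis=1)
        active = mask[:, t]
        dead |= active & (ct <= 0)
        safe = np.where((ct > 0) & active, ct, 1.0)
        alpha[:, t] = np.where(active[:, None], a / safe[:, None], alpha[:, t - 1])
        c[:, t] = safe

    loglik = np.where(dead, -np.inf, np.log(c).sum(axis=1))

    beta = np.zeros((n, tmax, N))
    last = lengths - 1
    beta[np.arange(n), last] = 1.0
    for t in range(tmax - 2, -1, -1):
        upd = (Bobs[:, t + 1] * beta[:, t + 1]) @ A.T / c[:, t + 1, None]
        interior = (t < last)[:, None]
        beta[:, t] = np.where(interior, upd, beta[:, t])

    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
    gamma *= mask[:, :, None]

    # xi summed over t: einsum of alpha_t with the backward-weighted next step
    w_next = Bobs[:, 1:] * beta[:, 1:] / c[:, 1:, None]
    w_next = w_next * mask[:, 1:, None]
    xi_sum = np.einsum("nti,ntj->nij", alpha[:, :-1] * mask[:, :-1, None], w_next)
    xi_sum = xi_sum * A[None, :, :]
    return loglik, gamma, xi_sum


def _batched_e_step(X, mask, lengths, mhmm: MHMMParams):
    """Full E step over padded data.

    Returns (resp (n,M), per-component loglik (n,M), stats SuffStats).
    """
    n = X.shape[0]
    M, N, K = mhmm.n_clusters, mhmm.n_states, mhmm.support_size
    comp_ll = np.empty((n, M))
    gammas = []
    xis = []
    for m, comp in enumerate(mhmm.components):
        ll, gamma, xi = _component_posteriors(X, mask, lengths, comp)
        comp_ll[:, m] = ll
        gammas.append(gamma)
        xis.append(xi)

    with np.errstate(divide="ignore"):
        log_joint = comp_ll + np.log(mhmm.weights)[None, :]
    norm = logsumexp(log_joint, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = np.nonzero(~np.isfinite(norm))[0]
        raise ValueError(
            f"sequences at positions {bad.tolist()} have zero likelihood "
            "under every mixture component"
        )
    resp = np.exp(log_joint - norm[:, None])
    total_ll = float(norm.sum())

    initial = np.empty((M, N))
    transition = np.empty((M, N, N))
    emission = np.zeros((M, N, K))
    flat_x = X[mask]
    for m in range(M):
        r = resp[:, m]
        initial[m] = (r[:, None] * gammas[m][:, 0]).sum(axis=0)
        transition[m] = (r[:, None, None] * xis[m]).sum(axis=0)
        g = gammas[m] * r[:, None, None]
        flat_g = g[mask]
        for s in range(N):
            emission[m, s] = np.bincount(flat_x, weights=flat_g[:, s], minlength=K)
    stats = SuffStats(
        resp_sum=resp.sum(axis=0),
        initial=initial,
        transition=transition,
        emission=emission,
        loglik=total_ll,
    )
    return resp, comp_ll, stats


# ---------------------------------------------------------------------------
# Public operations


def _counts_of(series_set) -> list[np.ndarray]:
    out = []
    for s in series_set:
        out.append(np.asarray(getattr(s, "counts", s), dtype=int))
    return out


def _ids_of(series_set) -> list[str]:
    return [str(getattr(s, "claim_id", i)) for i, s in enumerate(series_set)]


def e_step(series_set, mhmm: MHMMParams):
    """One E step: cluster posteriors and expected sufficient statistics."""
    counts = _counts_of(series_set)
    X, mask, lengths = _pack(counts, mhmm.support_size)
    resp, _, stats = _batched_e_step(X, mask, lengths, mhmm)
    ids = _ids_of(series_set)
    assignments = tuple(
        Assignment(claim_id=cid, posterior=resp[i], hard_label=int(np.argmax(resp[i])))
        for i, cid in enumerate(ids)
    )
    return assignments, stats


def m_step(stats: SuffStats) -> MHMMParams:
    """Closed-form maximum-likelihood update from expected counts.

    Emission rows get a small floor before renormalization so that EM never
    produces exact zeros (which would make later iterations non-finite).
    """
    if stats.resp_sum.sum() <= 0:
        raise ValueError("empty sufficient statistics")
    M, N, K = stats.emission.shape
    weights = stats.resp_sum / stats.resp_sum.sum()
    comps = []
    for m in range(M):
        pi = stats.initial[m] / max(stats.initial[m].sum(), 1e-300)
        a = stats.transition[m] + 1e-300
        a = a / a.sum(axis=1, keepdims=True)
        b = stats.emission[m] + EMISSION_FLOOR
        b = b / b.sum(axis=1, keepdims=True)
        comps.append(HMMParams(initial=pi, transition=a, emission=b))
    return MHMMParams(weights=weights, components=tuple(comps))


def total_log_likelihood(series_set, mhmm: MHMMParams) -> float:
    """Sum over series of log sum_m w_m p(x_{1:T} | component m)."""
    counts = _counts_of(series_set)
    X, mask, lengths = _pack(counts, mhmm.support_size)
    M = mhmm.n_clusters
    comp_ll = np.empty((X.shape[0], M))
    for m, comp in enumerate(mhmm.components):
        comp_ll[:, m], _, _ = _component_posteriors(X, mask, lengths, comp)
    with np.errstate(divide="ignore"):
        log_joint = comp_ll + np.log(mhmm.weights)[None, :]
    return float(logsumexp(log_joint, axis=1).sum())


def assign_clusters(series_set, mhmm: MHMMParams) -> tuple[Assignment, ...]:
    """Posterior cluster memberships (soft) and argmax hard labels."""
    assignments, _ = e_step(series_set, mhmm)
    return assignments


# ---------------------------------------------------------------------------
# Initialization and EM driver


def _random_params(M: int, N: int, K: int, rng: np.random.Generator) -> MHMMParams:
    """Dirichlet(2) random stochastic matrices for every factor."""
    comps = []
    for _ in range(M):
        pi = rng.dirichlet(np.full(N, 2.0))
        a = rng.dirichlet(np.full(N, 2.0), size=N)
        b = rng.dirichlet(np.full(K, 2.0), size=N)
        comps.append(HMMParams(initial=pi, transition=a, emission=b))
    w = rng.dirichlet(np.full(M, 2.0))
    return MHMMParams(weights=w, components=tuple(comps))


def _perturb(params: MHMMParams, rng: np.random.Generator, strength: float) -> MHMMParams:
    """Blend every stochastic row with a Dirichlet(1) draw.

    Used to diversify restarts around the structured initialization; EM from
    a fully random start rarely reaches a competitive optimum at M*N ~ 9,
    whereas perturbed structured starts explore the relevant basins.
    """
    s = float(strength)

    def mix(row):
        return (1 - s) * row + s * rng.dirichlet(np.ones(row.shape[-1]))

    comps = []
    for c in params.components:
        comps.append(
            HMMParams(
                initial=mix(c.initial),
                transition=np.vstack([mix(r) for r in c.transition]),
                emission=np.vstack([mix(r) for r in c.emission]),
            )
        )
    return MHMMParams(weights=mix(params.weights), components=tuple(comps))


def _series_groups(counts, M, rng):
    """K-means split of series by (mean count, log length, zero fraction)."""
    from sklearn.cluster import KMeans

    feats = np.array(
        [[c.mean(), np.log(len(c)), (c == 0).mean()] for c in counts], dtype=float
    )
    feats = (feats - feats.mean(axis=0)) / np.maximum(feats.std(axis=0), 1e-9)
    km = KMeans(n_clusters=M, n_init=4, random_state=int(rng.integers(2**31)))
    return km.fit_predict(feats)


def _params_from_levels(sel, level_seqs, N, K):
    """Empirical (pi, A, B) from provisional per-month state labels."""
    b_cnt = np.full((N, K), 0.5)
    a_cnt = np.full((N, N), 0.5)
    pi_cnt = np.full(N, 0.5)
    for c, lv in zip(sel, level_seqs):
        pi_cnt[lv[0]] += 1.0
        for s, v in zip(lv, c):
            b_cnt[s, v] += 1.0
        for s0, s1 in zip(lv[:-1], lv[1:]):
            a_cnt[s0, s1] += 1.0
    return HMMParams(
        initial=pi_cnt / pi_cnt.sum(),
        transition=a_cnt / a_cnt.sum(axis=1, keepdims=True),
        emission=b_cnt / b_cnt.sum(axis=1, keepdims=True),
    )


def _seeded_params(
    counts: list[np.ndarray],
    M: int,
    N: int,
    K: int,
    rng: np.random.Generator,
    flavor: str = "value",
) -> MHMMParams:
    """Structured initialization from a cheap hard clustering of the series.

    Series are partitioned into M groups by (mean count, log length, fraction
    of zero months); within each group every month gets a provisional state
    label and the component's (pi, A, B) start from the empirical statistics
    of those label sequences.  Two labeling flavors cover the two kinds of
    latent structure in utilization data:

    - "value": 1-d k-means levels on the month's count (states = count bands);
    - "time": position within the series (states = early/mid/late phases),
      which seeds a left-to-right progression that count bands cannot express
      when two states share a count range but differ in dwell.
    """
    from sklearn.cluster import KMeans

    groups = _series_groups(counts, M, rng)
    comps = []
    order = np.argsort([-np.sum(groups == m) for m in range(M)])
    for m in order:
        sel = [c for c, g in zip(counts, groups) if g == m]
        if not sel:
            sel = counts
        if flavor == "time":
            level_seqs = [
                np.minimum((np.arange(len(c)) * N) // max(len(c), 1), N - 1)
                for c in sel
            ]
        else:
            pooled = np.concatenate(sel).astype(float)
            if len(np.unique(pooled)) >= N:
                km1 = KMeans(
                    n_clusters=N, n_init=3, random_state=int(rng.integers(2**31))
                )
                km1.fit(pooled[:, None])
                centers = km1.cluster_centers_.ravel()
                level_seqs = [
                    np.argmin(np.abs(centers[None, :] - c[:, None]), axis=1)
                    for c in sel
                ]
            else:
                level_seqs = [np.minimum(c, N - 1) for c in sel]
        comps.append(_params_from_levels(sel, level_seqs, N, K))
    w = np.array([np.sum(groups == m) for m in order], dtype=float) + 1.0
    return MHMMParams(weights=w / w.sum(), components=tuple(comps))


def _canonicalize(mhmm: MHMMParams, resp: np.ndarray):
    """Reorder clusters by descending hard-assignment count (ties: old index)."""
    hard = resp.argmax(axis=1)
    sizes = np.bincount(hard, minlength=mhmm.n_clusters)
    order = np.lexsort((np.arange(mhmm.n_clusters), -sizes))
    new = MHMMParams(
        weights=mhmm.weights[order],
        components=tuple(mhmm.components[int(i)] for i in order),
    )
    return new, resp[:, order]


def fit_em(
    series_set,
    n_clusters: int,
    n_states: int,
    *,
    support_size: int | None = None,
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> FitResult:
    """Fit the mixture by EM with multiple restarts.

    The best restart by final total log-likelihood is returned, with clusters
    relabeled by descending membership count so that "cluster 1" is always the
    largest.  Convergence: relative improvement of the total log-likelihood
    below ``tol``.
    """
    if n_clusters < 1 or n_states < 1 or restarts < 1:
        raise ValueError("n_clusters, n_states and restarts must be >= 1")
    counts = _counts_of(series_set)
    if len(counts) < n_clusters:
        raise ValueError("need at least as many series as clusters")
    K = support_size or int(max(c.max() for c in counts)) + 1
    X, mask, lengths = _pack(counts, K)
    ids = _ids_of(series_set)

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = ss.spawn(restarts)
    best: tuple[float, FitResult] | None = None
    for r in range(restarts):
        rng = np.random.default_rng(child_seeds[r])
        if r == 0:
            params = _seeded_params(counts, n_clusters, n_states, K, rng, "value")
        elif r == 1:
            params = _seeded_params(counts, n_clusters, n_states, K, rng, "time")
        elif r == restarts - 1 and restarts >= 4:
            params = _random_params(n_clusters, n_states, K, rng)
        else:
            flavor = "time" if r % 2 else "value"
            base = _seeded_params(counts, n_clusters, n_states, K, rng, flavor)
            params = _perturb(base, rng, strength=0.2)
        trace = []
        converged = False
        resp = None
        for _ in range(max_iter):
            try:
                resp, _, stats = _batched_e_step(X, mask, lengths, params)
            except ValueError:
                break  # non-finite likelihood under this start; abandon restart
            trace.append(stats.loglik)
            if len(trace) > 1:
                prev, cur = trace[-2], trace[-1]
                if abs(cur - prev) <= tol * abs(prev):
                    converged = True
                    break
            params = m_step(stats)
        if not trace or resp is None:
            continue
        params, resp = _canonicalize(params, resp)
        result = FitResult(
            params=params,
            loglik_trace=np.array(trace),
            n_iter=len(trace),
            converged=converged,
            seed=seed,
            restart=r,
            assignments=tuple(
                Assignment(
                    claim_id=cid,
                    posterior=resp[i],
                    hard_label=int(np.argmax(resp[i])),
                )
                for i, cid in enumerate(ids)
            ),
        )
        if best is None or result.loglik > best[0]:
            best = (result.loglik, result)
    if best is None:
        raise RuntimeError("all EM restarts failed to produce a finite likelihood")
    return best[1]
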