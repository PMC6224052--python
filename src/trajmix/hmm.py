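"""Single hidden Markov model with categorical (count) emissions.

A trajectory is a sequence of monthly utilization counts ``x_{1:T}`` with
values in ``{0, ..., K-1}``.  The model assumes a latent state chain
``y_{1:T}`` with initial distribution ``pi``, transition matrix ``A`` and a
per-state categorical emission matrix ``B`` over the count support, so that

    p(x_{1:T}, y_{1:T}) = pi[y_1] * prod_t A[y_{t-1}, y_t] * prod_t B[y_t, x_t]

All public recursions run in log space (log-sum-exp) so that sequences of up
to ~100 months with small emission probabilities do not underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = ["HMMParams", "StatePath", "log_likelihood", "forward_backward", "viterbi"]

_ROW_TOL = 1e-12


def _check_stochastic(name: str, arr: np.ndarray) -> None:
    if np.any(arr < 0):
        raise ValueError(f"{name} has negative entries")
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError(f"{name} rows must sum to 1 (got {sums})")


@dataclass(frozen=True)
class HMMParams:
    """Parameters (pi, A, B) of an N-state HMM over count support {0..K-1}."""

    initial: np.ndarray  # (N,)
    transition: np.ndarray  # (N, N)
    emission: np.ndarray  # (N, K)

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial", np.asarray(self.initial, dtype=float))
        object.__setattr__(self, "transition", np.asarray(self.transition, dtype=float))
        object.__setattr__(self, "emission", np.asarray(self.emission, dtype=float))
        n = self.initial.shape[0]
        if self.transition.shape != (n, n):
            raise ValueError("transition must be N x N")
        if self.emission.shape[0] != n:
            raise ValueError("emission must have N rows")
        _check_stochastic("initial", self.initial)
        _check_stochastic("transition", self.transition)
        _check_stochastic("emission", self.emission)

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    @property
    def support_size(self) -> int:
        return self.emission.shape[1]

    def to_dict(self) -> dict:
        return {
            "N": self.n_states,
            "K": self.support_size,
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            initial=np.array(d["initial"], dtype=float),
            transition=np.array(d["transition"], dtype=float),
            emission=np.array(d["emission"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "HMMParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class StatePath:
    """A decoded state sequence and the log joint probability of (x, y)."""

    states: np.ndarray = field()
    log_joint: float = field()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=int))

    def __len__(self) -> int:
        return len(self.states)


def _validate_counts(counts: Sequence[int], hmm: HMMParams) -> np.ndarray:
    x = np.asarray(counts, dtype=int)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    bad = np.nonzero(x >= hmm.support_size)[0]
    if bad.size:
        raise ValueError(
            f"count {x[bad[0]]} at index {bad[0]} is outside the emission "
            f"support {{0..{hmm.support_size - 1}}}"
        )
    return x


def _log_params(hmm: HMMParams):
    with np.errstate(divide="ignore"):
        return (
            np.log(hmm.initial),
            np.log(hmm.transition),
            np.log(hmm.emission),
        )


def _log_forward(x: np.ndarray, hmm: HMMParams) -> np.ndarray:
    """Log forward lattice, shape (T, N): log p(x_{1:t}, y_t = s)."""
    log_pi, log_a, log_b = _log_params(hmm)
    T = x.size
    la = np.empty((T, hmm.n_states))
    la[0] = log_pi + log_b[:, x[0]]
    for t in range(1, T):
        la[t] = logsumexp(la[t - 1][:, None] + log_a, axis=0) + log_b[:, x[t]]
    return la


def log_likelihood(counts: Sequence[int], hmm: HMMParams) -> float:
    """Log marginal likelihood log p(x_{1:T}) via the forward recursion.

    Returns ``-inf`` when some observation has zero probability under every
    reachable state.
    """
    x = _validate_counts(counts, hmm)
    return float(logsumexp(_log_forward(x, hmm)[-1]))


def forward_backward(counts: Sequence[int], hmm: HMMParams):
    """State posteriors for one sequence.

    Returns
    -------
    gamma : (T, N) array, gamma[t, s] = p(y_t = s | x_{1:T})
    xi : (T-1, N, N) array, xi[t, s, s'] = p(y_t = s, y_{t+1} = s' | x_{1:T})
         (empty when T == 1)
    loglik : float
    """
    x = _validate_counts(counts, hmm)
    log_pi, log_a, log_b = _log_params(hmm)
    T, N = x.size, hmm.n_states

    la = _log_forward(x, hmm)
    lb = np.zeros((T, N))
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(log_a + log_b[:, x[t + 1]] + lb[t + 1], axis=1)

    ll = float(logsumexp(la[-1]))
    if not np.isfinite(ll):
        raise ValueError("sequence has zero probability under the model")
    gamma = np.exp(la + lb - ll)
    if T > 1:
        xi = np.exp(
            la[:-1, :, None]
            + log_a[None]
            + (log_b[:, x[1:]].T + lb[1:])[:, None, :]
            - ll
        )
    else:
        xi = np.empty((0, N, N))
    return gamma, xi, ll


def viterbi(counts: Sequence[int], hmm: HMMParams) -> StatePath:
    """Most probable state path, argmax_y p(x_{1:T}, y_{1:T}).

    Ties are broken toward the lower state index at every backtrack step, so
    the result is deterministic.
    """
    x = _validate_counts(counts, hmm)
    log_pi, log_a, log_b = _log_params(hmm)
    T, N = x.size, hmm.n_states

    delta = np.empty((T, N))
    psi = np.zeros((T, N), dtype=int)
    delta[0] = log_pi + log_b[:, x[0]]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_a  # (from, to)
        # argmax returns the lowest index among ties
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(N)] + log_b[:, x[t]]

    best_last = int(np.argmax(delta[-1]))
    log_joint = float(delta[-1, best_last])
    if not np.isfinite(log_joint):
        raise ValueError("all state paths have probability zero")
    states = np.empty(T, dtype=int)
    states[-1] = best_last
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return StatePath(states=states, log_joint=log_joint)
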