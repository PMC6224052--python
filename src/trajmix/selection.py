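"""Choice of the number of clusters M and states N by penalized likelihood.

The grid mirrors the usual practice of starting both M and N at 2 and
increasing in unit steps; every (M, N) pair is fitted by EM and scored with
BIC (AIC is recorded alongside for reporting).  The BIC sample size is the
total number of monthly observations (sum of series lengths), since each
month contributes one term to the likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixture import fit_em

logger = logging.getLogger(__name__)

__all__ = ["SelectionResult", "count_params", "bic", "aic", "grid_search"]


def count_params(M: int, N: int, K: int) -> int:
    """Free parameters of an M-component mixture of N-state HMMs over K symbols.

    (M-1) mixture weights plus, per component, (N-1) initial probabilities,
    N(N-1) transition and N(K-1) emission parameters.
    """
    if M < 1 or N < 1 or K < 2:
        raise ValueError("require M >= 1, N >= 1, K >= 2")
    return (M - 1) + M * ((N - 1) + N * (N - 1) + N * (K - 1))


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return n_params * np.log(n_obs) - 2.0 * loglik


def aic(loglik: float, n_params: int) -> float:
    return 2.0 * n_params - 2.0 * loglik


@dataclass(frozen=True)
class SelectionResult:
    grid: pd.DataFrame  # columns: M, N, loglik, n_params, bic, aic, ...
    selected: tuple[int, int]
    criterion: str = "bic"


def grid_search(
    series_set,
    M_values=(2, 3, 4, 5),
    N_values=(2, 3, 4),
    *,
    support_size: int | None = None,
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    criterion: str = "bic",
    keep_fits: bool = False,
):
    """Fit every (M, N) pair and select the minimum-BIC cell.

    Ties break toward smaller M, then smaller N.  Cells whose restarts all
    fail are excluded from selection and marked failed.  Returns a
    :class:`SelectionResult`; when ``keep_fits`` is true the fit of every cell
    is attached as ``result.fits[(M, N)]``.
    """
    M_values, N_values = list(M_values), list(N_values)
    if not M_values or not N_values:
        raise ValueError("M_values and N_values must be non-empty")
    counts = [np.asarray(getattr(s, "counts", s), dtype=int) for s in series_set]
    n_obs = int(sum(len(c) for c in counts))
    K = support_size or int(max(c.max() for c in counts)) + 1
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    cells = [(m, n) for m in M_values for n in N_values]
    child = ss.spawn(len(cells))
    rows, fits = [], {}
    for (m, n), cs in zip(cells, child):
        cell_seed = int(cs.generate_state(1)[0] % (2**31))
        try:
            fr = fit_em(
                series_set,
                m,
                n,
                support_size=K,
                restarts=restarts,
                tol=tol,
                max_iter=max_iter,
                seed=cell_seed,
            )
        except (RuntimeError, ValueError) as exc:
            logger.warning("grid cell (M=%d, N=%d) failed: %s", m, n, exc)
            rows.append(
                dict(M=m, N=n, loglik=np.nan, n_params=count_params(m, n, K),
                     bic=np.nan, aic=np.nan, converged=False, failed=True)
            )
            continue
        p = count_params(m, n, K)
        rows.append(
            dict(
                M=m,
                N=n,
                loglik=fr.loglik,
                n_params=p,
                bic=bic(fr.loglik, p, n_obs),
                aic=aic(fr.loglik, p),
                converged=fr.converged,
                failed=False,
            )
        )
        if keep_fits:
            fits[(m, n)] = fr
    grid = pd.DataFrame(rows)
    ok = grid[~grid["failed"]]
    if ok.empty:
        raise RuntimeError("every grid cell failed")
    crit = criterion.lower()
    # stable sort: criterion value, then smaller M, then smaller N
    ok = ok.sort_values([crit, "M", "N"], kind="mergesort")
    selected = (int(ok.iloc[0]["M"]), int(ok.iloc[0]["N"]))
    result = SelectionResult(grid=grid, selected=selected, criterion=crit)
    if keep_fits:
        object.__setattr__(result, "fits", fits)
    return result
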