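"""Cluster descriptions: stacked plots tables, state labels, state diagrams.

All outputs are plot-ready tidy tables or JSON-able dictionaries; rendering
is left to the caller (the tables carry everything the stacked plots and
state-diagram figures display).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import HMMParams, viterbi
from .mixture import FitResult, MHMMParams

__all__ = [
    "DEFAULT_LABEL_THRESHOLDS",
    "StackedMatrix",
    "StateDiagram",
    "label_states",
    "stacked_counts",
    "stacked_states",
    "state_diagram",
    "cluster_report",
    "decode_paths",
]

# Upper bin edges for the five qualitative state labels by expected
# emission value: < 0.5 "zero", < 2 "low", < 5 "medium", < 10 "high",
# otherwise "very high".
DEFAULT_LABEL_THRESHOLDS = (0.5, 2.0, 5.0, 10.0)
STATE_LABELS = ("zero", "low", "medium", "high", "very high")


@dataclass(frozen=True)
class StackedMatrix:
    """Month x value occupancy counts behind a stacked plot.

    ``table`` is tidy: columns (month, value, count), months starting at 1.
    ``active`` maps month -> number of series still observed at that month,
    which equals the column sum for every month (conservation).
    """

    axis: str  # "counts" or "states"
    table: pd.DataFrame
    active: pd.Series


@dataclass(frozen=True)
class StateDiagram:
    """Nodes (one per state: label, dwell, pie slices) and transition edges."""

    nodes: list[dict]
    edges: list[dict]

    def to_dict(self) -> dict:
        return {"nodes": self.nodes, "edges": self.edges}


def expected_emission_values(hmm: HMMParams) -> np.ndarray:
    return hmm.emission @ np.arange(hmm.support_size)


def label_states(
    mhmm: MHMMParams, thresholds=DEFAULT_LABEL_THRESHOLDS
) -> dict[tuple[int, int], str]:
    """Qualitative label of every (cluster, state) from its expected emission."""
    edges = np.asarray(thresholds, dtype=float)
    if len(edges) != 4 or np.any(np.diff(edges) <= 0):
        raise ValueError("thresholds must be 4 increasing bin edges")
    out = {}
    for m, comp in enumerate(mhmm.components):
        ev = expected_emission_values(comp)
        for s, e in enumerate(ev):
            out[(m, s)] = STATE_LABELS[int(np.searchsorted(edges, e, side="right"))]
    return out


def _stack(sequences, axis: str) -> StackedMatrix:
    sequences = [np.asarray(getattr(s, "counts", s), dtype=int) for s in sequences]
    if not sequences:
        raise ValueError("empty input")
    rows = []
    for seq in sequences:
        for t, v in enumerate(seq, start=1):
            rows.append((t, int(v)))
    df = pd.DataFrame(rows, columns=["month", "value"])
    table = (
        df.groupby(["month", "value"]).size().rename("count").reset_index()
    )
    active = df.groupby("month").size().rename("active")
    return StackedMatrix(axis=axis, table=table, active=active)


def stacked_counts(series_set) -> StackedMatrix:
    """Month x utilization-count occupancy over all series."""
    return _stack(series_set, "counts")


def stacked_states(state_paths) -> StackedMatrix:
    """Month x state occupancy over all decoded state paths."""
    return _stack(state_paths, "states")


def decode_paths(series_set, mhmm: MHMMParams, hard_labels) -> list[np.ndarray]:
    """Viterbi state path of every series under its assigned component."""
    return [
        viterbi(getattr(s, "counts", s), mhmm.components[int(z)]).states
        for s, z in zip(series_set, hard_labels)
    ]


def state_diagram(
    hmm: HMMParams,
    labels: dict[int, str] | None = None,
    collapse_threshold: float = 0.01,
) -> StateDiagram:
    """Pie-and-edge description of one component HMM.

    Emission probabilities below ``collapse_threshold`` are merged into a
    single "other" slice; expected dwell of state s is 1/(1 - A[s, s]) months
    (absorbing states are flagged); off-diagonal transitions at or above the
    threshold become edges.
    """
    nodes, edges = [], []
    N = hmm.n_states
    for s in range(N):
        row = hmm.emission[s]
        slices = {
            str(k): float(p) for k, p in enumerate(row) if p >= collapse_threshold
        }
        other = float(row[row < collapse_threshold].sum())
        if other > 0:
            slices["other"] = other
        selfp = float(hmm.transition[s, s])
        absorbing = selfp >= 1.0
        nodes.append(
            {
                "state": s,
                "label": labels.get(s) if labels else None,
                "dwell_months": np.inf if absorbing else 1.0 / (1.0 - selfp),
                "absorbing": absorbing,
                "self_transition": selfp,
                "slices": slices,
            }
        )
        for s2 in range(N):
            if s2 != s and hmm.transition[s, s2] >= collapse_threshold:
                edges.append(
                    {"from": s, "to": s2, "probability": float(hmm.transition[s, s2])}
                )
    return StateDiagram(nodes=nodes, edges=edges)


def cluster_report(fit: FitResult, series_set) -> dict[str, pd.DataFrame]:
    """Per-cluster summary tables.

    Returns ``{"clusters": ..., "zero_fraction": ...}`` where ``clusters`` has
    one row per cluster (size, share, mean length, mean yearly utilization)
    and ``zero_fraction`` gives, per cluster and month, the fraction of the
    cluster's series (among those at least that long) whose count is zero --
    the quantity behind statements like "at month 4 more than half have
    reached zero".
    """
    hard = np.array([a.hard_label for a in fit.assignments])
    counts = [np.asarray(getattr(s, "counts", s), dtype=int) for s in series_set]
    if len(hard) != len(counts):
        raise ValueError("assignments and series length mismatch")
    M = fit.params.n_clusters
    rows = []
    zf_rows = []
    for m in range(M):
        sel = [c for c, z in zip(counts, hard) if z == m]
        size = len(sel)
        if size == 0:
            rows.append(dict(cluster=m + 1, size=0, share=0.0,
                             mean_length=np.nan, mean_yearly_utilization=np.nan))
            continue
        lengths = np.array([len(c) for c in sel])
        totals = np.array([c.sum() for c in sel])
        rows.append(
            dict(
                cluster=m + 1,
                size=size,
                share=size / len(counts),
                mean_length=float(lengths.mean()),
                mean_yearly_utilization=float((totals / (lengths / 12.0)).mean()),
            )
        )
        tmax = lengths.max()
        for t in range(1, tmax + 1):
            at = [c[t - 1] for c in sel if len(c) >= t]
            zf_rows.append(
                dict(
                    cluster=m + 1,
                    month=t,
                    n_active=len(at),
                    zero_fraction=float(np.mean([v == 0 for v in at])),
                )
            )
    return {
        "clusters": pd.DataFrame(rows),
        "zero_fraction": pd.DataFrame(zf_rows),
    }
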