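"""Reading claim tables and building aligned monthly utilization series.

Input is a long-format event table (one row per service utilization, with a
three-level service category) plus a per-claim covariate table.  A claimant's
trajectory is the monthly count of utilizations of one chosen service,
aligned so that element 1 is the month of first utilization and the last
element the month of last utilization; interior months without events count 0.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UtilizationEvent",
    "UtilizationSeries",
    "ClaimCovariates",
    "build_series",
    "compute_elapsed_time",
    "filter_covariates",
    "read_events_csv",
    "read_covariates_csv",
    "series_to_frame",
    "frame_to_series",
    "write_series_csv",
    "read_series_csv",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class UtilizationEvent:
    """One service utilization (an office visit) on a calendar date."""

    claim_id: str
    service_date: date
    category_l1: str = ""
    category_l2: str = ""
    category_l3: str = ""


@dataclass(frozen=True)
class UtilizationSeries:
    """Monthly utilization counts for one claim, aligned at first utilization.

    ``counts[0]`` and ``counts[-1]`` are both >= 1 by construction (the series
    is trimmed to the first and last month with any utilization).
    """

    claim_id: str
    counts: np.ndarray
    start_month: pd.Period | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class ClaimCovariates:
    """Demographic, accident and injury covariates for one claim."""

    claim_id: str
    gender: str  # "male" / "female"
    age_group: str  # "<30", "30-40", "40-50", "50-60", ">60"
    role: str  # "driver", "passenger", "cyclist", "pedestrian", "witness"
    injury_flags: dict = field(default_factory=dict)
    accident_date: date | None = None
    elapsed_time_years: float = 0.0

    def __post_init__(self) -> None:
        if self.elapsed_time_years < 0:
            raise ValueError("elapsed_time_years must be non-negative")


def compute_elapsed_time(accident_date: date, first_utilization_date: date) -> float:
    """Years between the accident and the first service utilization.

    Defined as the day difference divided by 365.25.
    """
    days = (first_utilization_date - accident_date).days
    if days < 0:
        raise ValueError(
            f"first utilization {first_utilization_date} precedes accident "
            f"{accident_date}: inconsistent records"
        )
    return days / DAYS_PER_YEAR


def build_series(
    events,
    category: str | None = None,
    min_length: int = 2,
    *,
    clip_at: int | None = 25,
) -> list[UtilizationSeries]:
    """Aggregate events into per-claim monthly count series.

    Events are bucketed by the calendar month of ``service_date``; months
    between the first and last utilization with no events get count 0; series
    shorter than ``min_length`` months are dropped (and logged).  When
    ``category`` is given only events whose ``category_l3`` matches are kept.
    Counts at or above ``clip_at`` are clipped to ``clip_at - 1`` with a
    warning (the emission support is finite); pass ``clip_at=None`` to skip.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    events = list(events)
    if not events:
        raise ValueError("events must be non-empty")
    rows = []
    for ev in events:
        if category is not None and ev.category_l3 != category:
            continue
        if not isinstance(ev.service_date, date):
            warnings.warn(f"rejecting event with unparseable date: {ev!r}")
            continue
        rows.append((str(ev.claim_id), pd.Period(ev.service_date, freq="M")))
    if not rows:
        warnings.warn(f"no events with category_l3 == {category!r}")
        return []
    df = pd.DataFrame(rows, columns=["claim_id", "month"])
    out: list[UtilizationSeries] = []
    n_dropped = 0
    for cid, grp in df.groupby("claim_id", sort=True):
        first, last = grp["month"].min(), grp["month"].max()
        T = (last - first).n + 1
        counts = np.zeros(T, dtype=int)
        offsets = np.array([(m - first).n for m in grp["month"]])
        np.add.at(counts, offsets, 1)
        if T < min_length:
            n_dropped += 1
            logger.info("dropping claim %s: length %d < %d", cid, T, min_length)
            continue
        if clip_at is not None and counts.max() >= clip_at:
            warnings.warn(
                f"claim {cid}: counts >= {clip_at} clipped to {clip_at - 1}"
            )
            counts = np.minimum(counts, clip_at - 1)
        out.append(UtilizationSeries(claim_id=cid, counts=counts, start_month=first))
    if n_dropped:
        logger.info("dropped %d series shorter than %d months", n_dropped, min_length)
    return out


def filter_covariates(covariates: pd.DataFrame, threshold: float = 0.10) -> list[str]:
    """Names of covariates whose minority level covers >= ``threshold``.

    For a binary (two-level) covariate the minority-level share must reach the
    threshold; multi-level categoricals are retained when at least two levels
    reach it.  Numeric columns are always retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if covariates.empty:
        raise ValueError("covariate table is empty")
    kept = []
    for col in covariates.columns:
        if col == "claim_id":
            continue
        s = covariates[col].dropna()
        if s.empty:
            logger.info("dropping covariate %s: all missing", col)
            continue
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            kept.append(col)
            continue
        shares = s.value_counts(normalize=True)
        if (shares >= threshold).sum() >= 2:
            kept.append(col)
        else:
            logger.info(
                "dropping covariate %s: minority share %.3f < %.2f",
                col,
                1 - shares.iloc[0],
                threshold,
            )
    return kept


# ---------------------------------------------------------------------------
# CSV interfaces


def read_events_csv(path) -> list[UtilizationEvent]:
    """Long-format events: claim_id, service_date (ISO-8601), category_l1..l3."""
    df = pd.read_csv(path, dtype={"claim_id": str})
    events = []
    for row in df.itertuples(index=False):
        try:
            d = pd.Timestamp(row.service_date).date()
        except (ValueError, TypeError):
            warnings.warn(f"rejecting record with unparseable date: {row!r}")
            continue
        events.append(
            UtilizationEvent(
                claim_id=str(row.claim_id),
                service_date=d,
                category_l1=getattr(row, "category_l1", ""),
                category_l2=getattr(row, "category_l2", ""),
                category_l3=getattr(row, "category_l3", ""),
            )
        )
    return events


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"claim_id": str})
    if "claim_id" not in df.columns:
        raise ValueError("covariates CSV must have a claim_id column")
    return df


def series_to_frame(series: list[UtilizationSeries]) -> pd.DataFrame:
    """Wide layout: claim_id, start_month, t1..tT (ragged -> trailing blanks)."""
    tmax = max(len(s) for s in series)
    rows = []
    for s in series:
        row = {"claim_id": s.claim_id, "start_month": str(s.start_month or "")}
        for t, c in enumerate(s.counts, start=1):
            row[f"t{t}"] = c
        rows.append(row)
    cols = ["claim_id", "start_month"] + [f"t{t}" for t in range(1, tmax + 1)]
    return pd.DataFrame(rows, columns=cols)


def frame_to_series(df: pd.DataFrame) -> list[UtilizationSeries]:
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    tcols.sort(key=lambda c: int(c[1:]))
    out = []
    for row in df.itertuples(index=False):
        vals = []
        for c in tcols:
            v = getattr(row, c)
            if pd.isna(v):
                break
            vals.append(int(v))
        start = getattr(row, "start_month", "") or None
        out.append(
            UtilizationSeries(
                claim_id=str(row.claim_id),
                counts=np.array(vals, dtype=int),
                start_month=pd.Period(start, freq="M") if start else None,
            )
        )
    return out


def write_series_csv(series: list[UtilizationSeries], path, metadata: dict | None = None):
    df = series_to_frame(series)
    df.to_csv(path, index=False)
    side = {
        "n_series": len(series),
        "max_length": int(max(len(s) for s in series)),
        "total_utilizations": int(sum(int(s.counts.sum()) for s in series)),
    }
    if metadata:
        side.update(metadata)
    sidecar = str(path) + ".meta.json"
    with open(sidecar, "w") as f:
        json.dump(side, f, indent=2)


def read_series_csv(path) -> list[UtilizationSeries]:
    return frame_to_series(pd.read_csv(path, dtype={"claim_id": str}))
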