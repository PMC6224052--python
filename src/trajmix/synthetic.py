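"""Synthetic claims-like data generator with known ground truth.

Emulates the structure of a compensation agency's psychology-service
utilization data: ~788 variable-length monthly count series (2-106 months,
mean about 29), counts on {0..24}, three latent utilization groups with
shares about 67/27/6% ("brief", "intermediate", "sustained"), and per-claim
covariates (gender, age group, road-user role, injury flags, elapsed time
from accident to first utilization) whose joint distribution with the group
label follows a known multinomial-logit model.

Because every quantity downstream of this generator has a known truth, the
whole pipeline is testable by parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import UtilizationSeries
from .hmm import HMMParams
from .mixture import MHMMParams

__all__ = [
    "Scenario",
    "default_scenario",
    "sample_mhmm",
    "sample_covariates",
    "sample_labels_given_covariates",
    "COEF_NAMES",
]

MAX_LENGTH = 106
MIN_LENGTH = 2
SUPPORT = 25  # counts 0..24

COEF_NAMES = (
    "intercept",
    "male",
    "age_30_40",
    "age_40_50",
    "age_50_60",
    "age_gt60",
    "brain_head",
    "soft_tissue",
    "non_limb_fractures",
    "elapsed_years",
    "driver",
    "passenger",
    "cyclist",
    "witness",
)

AGE_GROUPS = ("<30", "30-40", "40-50", "50-60", ">60")
ROLES = ("driver", "passenger", "cyclist", "pedestrian", "witness")
INJURIES = (
    "brain_head",
    "concussion",
    "internal",
    "soft_tissue",
    "dislocation",
    "sprain_strains",
    "limb_fractures",
    "non_limb_fractures",
    "contusion_abrasion",
)

# Effects of the covariates on membership in clusters 2 ("intermediate") and
# 3 ("sustained") relative to cluster 1, per encoded column of COEF_NAMES.
# Intercepts are calibrated so that, under the covariate margins below, the
# implied marginal label shares match the mixture weights (0.67, 0.27, 0.06).
_EFFECTS_CLUSTER2 = (
    -2.139, -0.29, 0.65, 0.81, 0.60, 0.21, 0.58, 0.63, 0.13, -0.01,
    0.40, 0.42, 0.43, 1.34,
)
_EFFECTS_CLUSTER3 = (
    -3.744, -0.54, -0.10, -0.39, -2.04, -0.75, 2.90, 0.02, 1.28, 0.23,
    -0.55, 0.01, -0.36, 1.17,
)


def _truncated_poisson(lam: float, K: int = SUPPORT) -> np.ndarray:
    p = stats.poisson.pmf(np.arange(K), lam)
    return p / p.sum()


def _spiky(lo: int, probs, K: int = SUPPORT) -> np.ndarray:
    row = np.zeros(K)
    row[lo : lo + len(probs)] = probs
    return row / row.sum()


def _emission_row(kind: str) -> np.ndarray:
    """Emission distributions of the qualitative utilization levels.

    The "zero" state emits mostly zeros with some residual visits (mean
    0.48): real claimants parked at a near-zero level still show sporadic
    appointments, and a state emitting hard zeros is unidentifiable at the
    trimmed series boundary, whose counts are positive by construction.
    Month counts in the active states concentrate on a narrow band of
    typical appointment frequencies (e.g. about 3-4 per week for "very
    high"), so their distributions are peaked rather than Poisson-wide; the
    two "low" flavors differ in where the band sits within the low range.
    """
    if kind == "zero":
        return _spiky(0, (0.62, 0.30, 0.06, 0.02))
    if kind == "low":
        return _spiky(0, (0.10, 0.55, 0.30, 0.05))  # mean 1.3
    if kind == "low_upper":
        return _truncated_poisson(1.8)
    if kind == "medium":
        return _spiky(2, (0.15, 0.30, 0.30, 0.15, 0.10))  # mean 3.75
    if kind == "high":
        return _truncated_poisson(8.0)
    if kind == "high_peaked":
        return _spiky(5, (0.05, 0.15, 0.30, 0.30, 0.15, 0.05))  # mean 7.5
    if kind == "very_high":
        return _spiky(12, (0.05, 0.15, 0.30, 0.30, 0.15, 0.05))  # mean 14.5
    raise ValueError(f"unknown emission kind: {kind}")


@dataclass(frozen=True)
class Scenario:
    """A fully specified generative truth for series and covariates."""

    true_model: MHMMParams
    length_means: tuple[float, ...]  # per-cluster mean of the untruncated law
    length_dispersion: tuple[float, ...]  # negative-binomial r per cluster
    covariate_effects: pd.DataFrame  # rows = COEF_NAMES, cols = cluster 2..M
    covariate_margins: dict
    elapsed_mean_years: float = 0.5
    state_kinds: tuple[tuple[str, ...], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        M = self.true_model.n_clusters
        if len(self.length_means) != M or len(self.length_dispersion) != M:
            raise ValueError("length parameters must have one entry per cluster")
        if list(self.covariate_effects.index) != list(COEF_NAMES):
            raise ValueError("covariate_effects rows must follow COEF_NAMES")
        if self.covariate_effects.shape[1] != M - 1:
            raise ValueError("covariate_effects needs one column per non-reference cluster")

    def length_pmf(self, cluster: int) -> np.ndarray:
        """Pmf of T over {2..106}: shifted negative binomial, truncated."""
        mean_excess = self.length_means[cluster] - MIN_LENGTH
        r = self.length_dispersion[cluster]
        p = r / (r + mean_excess)
        pmf = stats.nbinom.pmf(np.arange(0, MAX_LENGTH - MIN_LENGTH + 1), r, p)
        return pmf / pmf.sum()

    def mean_length(self) -> float:
        """Analytic mean series length under the mixture, after truncation."""
        support = np.arange(MIN_LENGTH, MAX_LENGTH + 1)
        return float(
            sum(
                w * (self.length_pmf(m) @ support)
                for m, w in enumerate(self.true_model.weights)
            )
        )


def default_scenario(seed: int = 0) -> Scenario:
    """Three clusters x three states over counts {0..24}.

    Cluster 1 ("brief", weight 0.67): short series, medium -> low -> zero.
    Cluster 2 ("intermediate", 0.27): moderate lengths, high -> low -> zero.
    Cluster 3 ("sustained", 0.06): long series, very-high -> high -> zero.
    Off-diagonal transition probabilities follow the narrative values of the
    state diagrams (0.28/0.13/0.15; 0.068/0.062; 0.057/0.045).
    """
    kinds = (
        ("medium", "low", "zero"),
        ("high", "low_upper", "zero"),
        ("very_high", "high_peaked", "zero"),
    )
    A1 = np.array(
        [
            [0.70, 0.28, 0.02],
            [0.15, 0.72, 0.13],
            [0.07, 0.13, 0.80],
        ]
    )
    A2 = np.array(
        [
            [0.920, 0.068, 0.012],
            [0.028, 0.910, 0.062],
            [0.005, 0.015, 0.980],
        ]
    )
    A3 = np.array(
        [
            [0.940, 0.057, 0.003],
            [0.090, 0.865, 0.045],
            [0.050, 0.080, 0.870],
        ]
    )
    pis = (np.array([0.9, 0.1, 0.0]), np.array([0.95, 0.05, 0.0]), np.array([0.6, 0.4, 0.0]))
    comps = tuple(
        HMMParams(
            initial=pi,
            transition=a,
            emission=np.vstack([_emission_row(k) for k in ks]),
        )
        for pi, a, ks in zip(pis, (A1, A2, A3), kinds)
    )
    model = MHMMParams(weights=np.array([0.67, 0.27, 0.06]), components=comps)
    effects = pd.DataFrame(
        {2: _EFFECTS_CLUSTER2, 3: _EFFECTS_CLUSTER3}, index=list(COEF_NAMES)
    )
    margins = {
        "gender": {"male": 0.48, "female": 0.52},
        "age_group": dict(zip(AGE_GROUPS, (0.35, 0.22, 0.21, 0.13, 0.09))),
        "role": dict(zip(ROLES, (0.47, 0.23, 0.16, 0.11, 0.03))),
        "injuries": {
            "brain_head": 0.24,
            "concussion": 0.19,
            "internal": 0.29,
            "soft_tissue": 0.53,
            "dislocation": 0.19,
            "sprain_strains": 0.24,
            "limb_fractures": 0.37,
            "non_limb_fractures": 0.38,
            "contusion_abrasion": 0.67,
        },
    }
    return Scenario(
        true_model=model,
        length_means=(21.0, 44.0, 80.0),
        length_dispersion=(2.0, 4.0, 8.0),
        covariate_effects=effects,
        covariate_margins=margins,
        state_kinds=kinds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Series sampling


def _sample_categorical(rng, pmf, size=None):
    return rng.choice(len(pmf), size=size, p=np.asarray(pmf) / np.sum(pmf))


def sample_mhmm(scenario: Scenario, n: int, seed: int | None = None):
    """Draw n series from the scenario's mixture of HMMs.

    For each series: z ~ w, T ~ cluster length law, y_1 ~ pi_z, y_t ~ A_z,
    x_t ~ B_z; then the emissions at t=1 and t=T are redrawn conditional on
    positivity (the observed series is trimmed to first/last utilization, so
    its endpoints are >= 1 by definition).

    Returns (series, labels, state_paths); fully reproducible given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = scenario.true_model
    if np.any(model.weights < 0):
        raise ValueError("degenerate mixture weights")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    M = model.n_clusters
    pmfs = [scenario.length_pmf(m) for m in range(M)]
    labels = rng.choice(M, size=n, p=model.weights)
    series, paths = [], []
    n_truncated = 0
    for i in range(n):
        z = int(labels[i])
        comp = model.components[z]
        T = MIN_LENGTH + int(_sample_categorical(rng, pmfs[z]))
        y = np.empty(T, dtype=int)
        y[0] = _sample_categorical(rng, comp.initial)
        for t in range(1, T):
            y[t] = _sample_categorical(rng, comp.transition[y[t - 1]])
        x = np.empty(T, dtype=int)
        for t in range(T):
            x[t] = _sample_categorical(rng, comp.emission[y[t]])
        for t in (0, T - 1):
            if x[t] == 0:
                cond = comp.emission[y[t]].copy()
                cond[0] = 0.0
                if cond.sum() <= 0:
                    raise ValueError(
                        f"state {y[t]} of cluster {z} cannot emit a positive count"
                    )
                x[t] = _sample_categorical(rng, cond)
                n_truncated += 1
        series.append(
            UtilizationSeries(claim_id=f"S{i:05d}", counts=x, start_month=None)
        )
        paths.append(y)
    if n_truncated:
        import logging

        logging.getLogger(__name__).info(
            "resampled %d endpoint emissions conditional on positivity", n_truncated
        )
    return series, labels, paths


# ---------------------------------------------------------------------------
# Covariate sampling


def _draw_raw_covariates(rng, scenario: Scenario, claim_id: str) -> dict:
    m = scenario.covariate_margins
    genders = list(m["gender"])
    row = {
        "claim_id": claim_id,
        "gender": genders[_sample_categorical(rng, list(m["gender"].values()))],
        "age_group": AGE_GROUPS[
            _sample_categorical(rng, [m["age_group"][a] for a in AGE_GROUPS])
        ],
        "role": ROLES[_sample_categorical(rng, [m["role"][r] for r in ROLES])],
        "elapsed_years": float(rng.exponential(scenario.elapsed_mean_years)),
    }
    for inj in INJURIES:
        row[inj] = int(rng.random() < m["injuries"][inj])
    return row


def _encode_row(row: dict) -> np.ndarray:
    """Encode one covariate draw in the COEF_NAMES order (intercept first)."""
    v = np.zeros(len(COEF_NAMES))
    v[0] = 1.0
    v[1] = 1.0 if row["gender"] == "male" else 0.0
    for j, a in enumerate(AGE_GROUPS[1:], start=2):
        v[j] = 1.0 if row["age_group"] == a else 0.0
    v[6] = row["brain_head"]
    v[7] = row["soft_tissue"]
    v[8] = row["non_limb_fractures"]
    v[9] = row["elapsed_years"]
    for j, r in enumerate(("driver", "passenger", "cyclist"), start=10):
        v[j] = 1.0 if row["role"] == r else 0.0
    v[13] = 1.0 if row["role"] == "witness" else 0.0
    return v


def _membership_probs(v: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """p(z | covariates) under the scenario logit; cluster 1 is reference."""
    eta = np.concatenate([[0.0], v @ effects])
    eta -= eta.max()
    p = np.exp(eta)
    return p / p.sum()


def sample_covariates(
    labels,
    scenario: Scenario,
    seed: int | None = None,
    max_attempts: int = 100_000,
    accident_year: int = 2009,
) -> pd.DataFrame:
    """Draw a covariate table consistent with the given cluster labels.

    For each claim with label z, candidate covariates c are drawn from the
    scenario margins and accepted with probability p(z | c) under the
    scenario's multinomial logit; this is exact rejection sampling from
    p(c | z).  Accident dates are spread uniformly over ``accident_year`` and
    the first-utilization date is the accident date plus the elapsed time.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    effects = scenario.covariate_effects.to_numpy()
    rows = []
    for i, z in enumerate(np.asarray(labels, dtype=int)):
        for attempt in range(max_attempts):
            row = _draw_raw_covariates(rng, scenario, f"S{i:05d}")
            p = _membership_probs(_encode_row(row), effects)
            if rng.random() < p[z]:
                break
        else:
            raise RuntimeError(
                f"could not sample covariates for label {z} in {max_attempts} attempts: "
                "margins and effects are incompatible"
            )
        acc = date(accident_year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        row["accident_date"] = acc.isoformat()
        row["first_utilization_date"] = (
            acc + timedelta(days=round(row["elapsed_years"] * 365.25))
        ).isoformat()
        rows.append(row)
    cols = (
        ["claim_id", "gender", "age_group", "role"]
        + list(INJURIES)
        + ["elapsed_years", "accident_date", "first_utilization_date"]
    )
    return pd.DataFrame(rows, columns=cols)


def sample_labels_given_covariates(
    scenario: Scenario, n: int, seed: int | None = None
):
    """Forward generator: covariates from margins, then z ~ logit(covariates).

    Exactly matched to what multinomial regression estimates, so coefficient
    recovery against the scenario effects is well-posed.  Returns
    (covariates DataFrame, labels array in {0..M-1}).
    """
    rng = np.random.default_rng(scenario.seed + 2 if seed is None else seed)
    effects = scenario.covariate_effects.to_numpy()
    rows, labels = [], np.empty(n, dtype=int)
    for i in range(n):
        row = _draw_raw_covariates(rng, scenario, f"S{i:05d}")
        p = _membership_probs(_encode_row(row), effects)
        labels[i] = _sample_categorical(rng, p)
        rows.append(row)
    cols = ["claim_id", "gender", "age_group", "role"] + list(INJURIES) + [
        "elapsed_years"
    ]
    return pd.DataFrame(rows, columns=cols), labels
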