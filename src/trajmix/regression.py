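"""Multinomial logistic regression of cluster membership on claim covariates.

The largest cluster serves as the reference response; a separate logit is
estimated for every other cluster.  Covariate encoding follows the claims
analysis conventions: gender male = 1 (female reference), age-group dummies
against "<30", road-user-role dummies against "pedestrian", binary injury
flags against their alternative, and elapsed time (accident to first
utilization) in years as a numeric input.  Four nested covariate sets are
fitted: demographics; + injuries; + elapsed time; + roles.

Estimation is delegated to statsmodels' MNLogit (Newton-Raphson); this
module owns the encoding, reference handling, Wald stars and rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionSpec",
    "RegressionResult",
    "encode_covariates",
    "fit_multinomial",
    "model_suite",
    "significance_stars",
    "render_table",
]

AGE_LEVELS = ("<30", "30-40", "40-50", "50-60", ">60")
ROLE_LEVELS = ("driver", "passenger", "cyclist", "pedestrian", "witness")

MODEL_COVARIATES = {
    1: ("gender", "age_group"),
    2: ("gender", "age_group", "brain_head", "soft_tissue", "non_limb_fractures"),
    3: (
        "gender",
        "age_group",
        "brain_head",
        "soft_tissue",
        "non_limb_fractures",
        "elapsed_years",
    ),
    4: (
        "gender",
        "age_group",
        "brain_head",
        "soft_tissue",
        "non_limb_fractures",
        "elapsed_years",
        "role",
    ),
}


@dataclass(frozen=True)
class RegressionSpec:
    """Reference choices and nested covariate sets for the model suite."""

    reference_cluster: int = 0  # canonical order puts the largest cluster first
    age_reference: str = "<30"
    role_reference: str = "pedestrian"
    gender_level: str = "male"  # coded 1; the alternative is the reference
    models: dict = field(default_factory=lambda: dict(MODEL_COVARIATES))


@dataclass(frozen=True)
class RegressionResult:
    """Long-format coefficient table plus fit metadata."""

    table: pd.DataFrame  # cluster, covariate, estimate, se, p, stars
    loglik: float
    n_used: int
    model_id: int | None = None


def significance_stars(p: float) -> str:
    """Star code: *** p<0.01, ** p<0.05, * p<0.1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def encode_covariates(
    covariates: pd.DataFrame,
    model_covariates=MODEL_COVARIATES[4],
    spec: RegressionSpec | None = None,
) -> pd.DataFrame:
    """Design matrix with intercept, dummies against the reference levels.

    Rows with a missing value in any modeled covariate are dropped
    (complete-case analysis); the returned frame keeps the original index of
    the retained rows so labels can be aligned.
    """
    spec = spec or RegressionSpec()
    cols = {}
    used = [c for c in model_covariates]
    df = covariates.dropna(subset=[c for c in used if c in covariates.columns])
    cols["intercept"] = np.ones(len(df))
    for cov in model_covariates:
        if cov == "gender":
            cols["gender_male"] = (df["gender"] == spec.gender_level).astype(float)
        elif cov == "age_group":
            for lvl in AGE_LEVELS:
                if lvl == spec.age_reference:
                    continue
                cols[f"age_{lvl}"] = (df["age_group"] == lvl).astype(float)
        elif cov == "role":
            for lvl in ROLE_LEVELS:
                if lvl == spec.role_reference:
                    continue
                cols[f"role_{lvl}"] = (df["role"] == lvl).astype(float)
        elif cov == "elapsed_years":
            cols["elapsed_years"] = df["elapsed_years"].astype(float)
        else:  # binary injury flag
            cols[cov] = df[cov].astype(float)
    return pd.DataFrame(cols, index=df.index)


def fit_multinomial(
    labels,
    design: pd.DataFrame,
    reference_cluster: int = 0,
    *,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> RegressionResult:
    """Maximum-likelihood multinomial logit with Wald tests.

    ``labels`` are cluster indices; ``reference_cluster`` is remapped to
    category 0 so its coefficients are identically zero.  Raises on
    rank-deficient designs (naming the collinear columns) and on apparent
    perfect separation (diverging coefficients).
    """
    labels = np.asarray(labels)
    if len(labels) != len(design):
        raise ValueError("labels and design length mismatch")
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("need at least two clusters present")
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of columns that do not extend the rank
        bad = []
        cur: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, cur + [j]]) == len(cur):
                bad.append(design.columns[j])
            else:
                cur.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    # remap: reference first, remaining clusters in ascending order
    others = [c for c in present if c != reference_cluster]
    mapping = {reference_cluster: 0, **{c: i + 1 for i, c in enumerate(others)}}
    y = np.array([mapping[v] for v in labels])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(y, X)
        try:
            res = model.fit(method="newton", maxiter=maxiter, gtol=tol, disp=False)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "apparent perfect separation: the observed information matrix "
                "became singular during Newton iterations"
            ) from exc
    params = np.asarray(res.params)  # (k_exog, M-1)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 30:
        j, m = np.unravel_index(np.nanargmax(np.abs(params)), params.shape)
        raise ValueError(
            f"apparent perfect separation on covariate {design.columns[j]!r} "
            f"(cluster {others[m]})"
        )
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    rows = []
    for m, cluster in enumerate(others):
        for j, name in enumerate(design.columns):
            p = float(pvals[j, m])
            rows.append(
                dict(
                    cluster=int(cluster) + 1,  # 1-based cluster numbering
                    covariate=name,
                    estimate=float(params[j, m]),
                    se=float(bse[j, m]),
                    p=p,
                    stars=significance_stars(p),
                )
            )
    return RegressionResult(
        table=pd.DataFrame(rows), loglik=float(res.llf), n_used=len(y)
    )


def model_suite(
    labels,
    covariates: pd.DataFrame,
    spec: RegressionSpec | None = None,
) -> dict[int, RegressionResult]:
    """Fit the four nested covariate sets on identical complete cases.

    Complete cases are determined by the largest model so that the
    log-likelihoods of nested models are comparable.
    """
    spec = spec or RegressionSpec()
    labels = np.asarray(labels)
    largest = spec.models[max(spec.models)]
    base = encode_covariates(covariates, largest, spec)
    idx = base.index
    out = {}
    for mid, covs in sorted(spec.models.items()):
        design = encode_covariates(covariates.loc[idx], covs, spec)
        res = fit_multinomial(labels[idx], design, spec.reference_cluster)
        out[mid] = RegressionResult(
            table=res.table, loglik=res.loglik, n_used=res.n_used, model_id=mid
        )
    return out


def render_table(suite: dict[int, RegressionResult]) -> str:
    """Aligned text table: one row per cluster:covariate, one column per model.

    Cells show ``estimate<stars>(se)``; covariates absent from a model are
    blank.  Non-reference clusters are prefixed "2:", "3:", ... as in the
    usual presentation of multinomial fits.
    """
    all_rows: list[tuple[int, str]] = []
    for res in suite.values():
        for _, r in res.table.iterrows():
            key = (r["cluster"], r["covariate"])
            if key not in all_rows:
                all_rows.append(key)
    # order: covariate blocks in first-appearance order, clusters interleaved
    cov_order: list[str] = []
    for c, cov in all_rows:
        if cov not in cov_order:
            cov_order.append(cov)
    clusters = sorted({c for c, _ in all_rows})
    lines = []
    header = ["", *[f"Model ({mid})" for mid in sorted(suite)]]
    widths = [24] + [18] * len(suite)
    lines.append("".join(h.ljust(w) for h, w in zip(header, widths)))
    for cov in cov_order:
        for cl in clusters:
            cells = [f"{cl}:{cov}"]
            for mid in sorted(suite):
                t = suite[mid].table
                hit = t[(t["cluster"] == cl) & (t["covariate"] == cov)]
                if hit.empty:
                    cells.append("")
                else:
                    r = hit.iloc[0]
                    cells.append(f"{r['estimate']:.2f}{r['stars']}({r['se']:.2f})")
            lines.append("".join(c.ljust(w) for c, w in zip(cells, widths)))
    lines.append("Note: *p<0.1; **p<0.05; ***p<0.01")
    return "\n".join(lines)
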