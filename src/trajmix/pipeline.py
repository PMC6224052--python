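"""End-to-end orchestration: data -> fit/selection -> summaries -> baselines
-> regression, with a single config and reproducible seeding.

Every stage writes file artifacts with stable formats so stages can be rerun
independently; ``run`` sequences them all and emits a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import clara, fcm, pad_series, pam, validation_report
from .data_io import (
    build_series,
    read_covariates_csv,
    read_events_csv,
    write_series_csv,
)
from .mixture import fit_em
from .regression import RegressionSpec, model_suite, render_table
from .selection import grid_search
from .summaries import (
    cluster_report,
    decode_paths,
    label_states,
    stacked_counts,
    stacked_states,
    state_diagram,
)
from .synthetic import default_scenario, sample_covariates, sample_mhmm

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Exactly one of ``events_csv`` (with ``covariates_csv``) or
    ``synthetic_n`` must be set.
    """

    out_dir: str = "trajmix_out"
    seed: int = 0
    # real-data inputs
    events_csv: str | None = None
    covariates_csv: str | None = None
    category: str = "psychology"
    min_length: int = 2
    # synthetic input
    synthetic_n: int | None = None
    # model selection / fit
    M_values: tuple[int, ...] = (2, 3, 4, 5)
    N_values: tuple[int, ...] = (2, 3, 4)
    restarts: int = 5
    tol: float = 1e-6
    max_iter: int = 500
    # stage toggles
    run_selection: bool = True
    run_baselines: bool = True
    run_regression: bool = True
    clara_sample_size: int = 50
    fcm_fuzzifier: float = 2.0
    collapse_threshold: float = 0.01

    def __post_init__(self) -> None:
        real = self.events_csv is not None
        if real == (self.synthetic_n is not None):
            raise ValueError(
                "exactly one of events_csv or synthetic_n must be set"
            )
        if self.min_length < 1 or self.restarts < 1:
            raise ValueError("min_length and restarts must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("M_values", "N_values"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["M_values"] = list(self.M_values)
        d["N_values"] = list(self.N_values)
        return d


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": rng_seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": [],
    }

    # ---- data stage
    t0 = _stage("data")
    covariates = None
    if config.synthetic_n is not None:
        scenario = default_scenario(seed=rng_seed)
        series, true_labels, _ = sample_mhmm(scenario, config.synthetic_n, seed=rng_seed)
        covariates = sample_covariates(true_labels, scenario, seed=rng_seed + 1)
        np.savetxt(out / "true_labels.csv", true_labels, fmt="%d", header="label")
        support = scenario.true_model.support_size
    else:
        events = read_events_csv(config.events_csv)
        series = build_series(events, config.category, config.min_length)
        if not series:
            raise RuntimeError("data stage produced no series")
        if config.covariates_csv:
            covariates = read_covariates_csv(config.covariates_csv)
        support = max(int(s.counts.max()) for s in series) + 1
    write_series_csv(series, out / "series.csv", {"seed": rng_seed})
    manifest["stages"].append({"name": "data", "seconds": time.time() - t0,
                               "n_series": len(series)})

    # ---- fit / selection stage
    t0 = _stage("fit")
    single_cell = len(config.M_values) == 1 and len(config.N_values) == 1
    if config.run_selection and not single_cell:
        sel = grid_search(
            series,
            config.M_values,
            config.N_values,
            support_size=support,
            restarts=config.restarts,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=rng_seed,
            keep_fits=True,
        )
        sel.grid.to_csv(out / "selection_grid.csv", index=False)
        (out / "selection.json").write_text(
            json.dumps({"selected": list(sel.selected), "criterion": sel.criterion})
        )
        fit = sel.fits[sel.selected]
    else:
        m, n = config.M_values[0], config.N_values[0]
        fit = fit_em(
            series,
            m,
            n,
            support_size=support,
            restarts=config.restarts,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=rng_seed,
        )
    (out / "model.json").write_text(fit.params.to_json())
    hard = np.array([a.hard_label for a in fit.assignments])
    pd.DataFrame(
        {
            "claim_id": [a.claim_id for a in fit.assignments],
            **{
                f"p_{m + 1}": [float(a.posterior[m]) for a in fit.assignments]
                for m in range(fit.params.n_clusters)
            },
            "hard_label": hard + 1,
        }
    ).to_csv(out / "assignments.csv", index=False)
    manifest["stages"].append(
        {"name": "fit", "seconds": time.time() - t0,
         "M": fit.params.n_clusters, "N": fit.params.n_states,
         "loglik": fit.loglik, "converged": bool(fit.converged)}
    )

    # ---- summaries stage
    t0 = _stage("summaries")
    labels = label_states(fit.params)
    paths = decode_paths(series, fit.params, hard)
    stacked_counts(series).table.to_csv(out / "stacked_counts.csv", index=False)
    stacked_states(paths).table.to_csv(out / "stacked_states.csv", index=False)
    diagrams = {
        f"cluster_{m + 1}": state_diagram(
            comp,
            {s: labels[(m, s)] for s in range(comp.n_states)},
            config.collapse_threshold,
        ).to_dict()
        for m, comp in enumerate(fit.params.components)
    }
    def _clean(o):
        if isinstance(o, float) and np.isinf(o):
            return "inf"
        if isinstance(o, dict):
            return {k: _clean(v) for k, v in o.items()}
        if isinstance(o, list):
            return [_clean(v) for v in o]
        return o
    (out / "state_diagrams.json").write_text(json.dumps(_clean(diagrams), indent=2))
    report = cluster_report(fit, series)
    report["clusters"].to_csv(out / "cluster_summary.csv", index=False)
    report["zero_fraction"].to_csv(out / "zero_fraction.csv", index=False)
    manifest["stages"].append({"name": "summaries", "seconds": time.time() - t0})

    # ---- baselines stage
    if config.run_baselines:
        t0 = _stage("baselines")
        vec = pad_series(series)
        M = fit.params.n_clusters
        pam_labels, _ = pam(vec.distances, M)
        clara_labels, _ = clara(
            vec.distances, M, sample_size=config.clara_sample_size, seed=rng_seed
        )
        U, _ = fcm(vec.vectors, M, fuzzifier=config.fcm_fuzzifier, seed=rng_seed)
        fcm_labels = U.argmax(axis=1)
        rep = validation_report(
            vec.distances,
            {"mhmm": hard, "pam": pam_labels, "clara": clara_labels, "fcm": fcm_labels},
        )
        rep.to_csv(out / "validation_report.csv", index=False)
        from .baselines import mds_2d

        coords = mds_2d(vec.distances)
        pd.DataFrame(
            {"claim_id": vec.claim_ids, "x": coords[:, 0], "y": coords[:, 1],
             "mhmm": hard + 1, "pam": pam_labels + 1, "clara": clara_labels + 1,
             "fcm": fcm_labels + 1}
        ).to_csv(out / "mds_coordinates.csv", index=False)
        manifest["stages"].append({"name": "baselines", "seconds": time.time() - t0})

    # ---- regression stage
    if config.run_regression and covariates is not None:
        t0 = _stage("regression")
        cov = covariates.reset_index(drop=True)
        try:
            suite = model_suite(hard, cov, RegressionSpec())
        except ValueError as exc:
            # small samples can separate on sparse dummies; record and go on
            logger.warning("regression stage failed: %s", exc)
            (out / "regression_failed.txt").write_text(str(exc))
            manifest["stages"].append(
                {"name": "regression", "seconds": time.time() - t0,
                 "failed": True, "error": str(exc)}
            )
        else:
            long = pd.concat(
                [r.table.assign(model=mid) for mid, r in suite.items()],
                ignore_index=True,
            )
            long.to_csv(out / "regression.csv", index=False)
            (out / "regression.txt").write_text(render_table(suite))
            manifest["stages"].append(
                {"name": "regression", "seconds": time.time() - t0}
            )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
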