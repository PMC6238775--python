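"""End-to-end study pipeline over the three research questions.

Q1 — are learning performances consistent from chick to adult?
     Per-individual logistic curves on a common 20-trial window in both
     phases; one-way ICC of ``x_final`` and of ``y80`` across phases.
Q2 — does chick learning performance predict adult social rank?
     Spearman correlation of each chick metric against the adult mean
     Elo-rating.
Q3 — does rank-related variation persist under a rank manipulation?
     Trial-level binomial GLMM of adult choices (trials 2–100) with
     rank, trial, their interaction and housing covariates; plus the
     SG-vs-PD display-rate contrast validating the manipulation.

Every stage writes tidy CSVs; :func:`run_all` runs the whole pipeline
on synthetic cohorts and assembles a plain-text report, deterministic
under the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import displays, glmm, learning, synthetic
from .hierarchy import EloConfig, estimate_hierarchy
from .io_formats import RunConfig
from .stats import ICCResult, SpearmanResult, icc_oneway, spearman


@dataclasses.dataclass
class Q1Result:
    icc_x_final: ICCResult
    icc_y80: ICCResult
    metrics: pd.DataFrame  # wide per-individual chick/adult metrics
    n_pairs_x_final: int
    n_pairs_y80: int


@dataclasses.dataclass
class Q2Result:
    spearman_x_final: SpearmanResult
    spearman_y80: SpearmanResult
    table: pd.DataFrame


@dataclasses.dataclass
class Q3Result:
    full_fit: glmm.GLMMFit
    full_lrts: pd.DataFrame
    minimal_fit: glmm.GLMMFit
    elimination: pd.DataFrame
    random_structure: glmm.LRTResult
    manipulation: dict[str, displays.ContrastResult] | None


def run_q1(
    chick_trials: pd.DataFrame,
    adult_trials: pd.DataFrame,
    window: int = 20,
) -> Q1Result:
    """Chick→adult consistency of both learning metrics."""
    fits = learning.fit_cohort(
        pd.concat([chick_trials, adult_trials], ignore_index=True), window=window
    )
    wide = fits.pivot(index="individual", columns="phase", values=["x_final", "y80"])
    wide.columns = [f"{p}_{m}" for m, p in wide.columns]
    both = wide.dropna(subset=["chick_x_final", "adult_x_final"])
    if len(both) < 3:
        raise ValueError("fewer than 3 individuals tested in both phases")
    icc_x = icc_oneway(list(zip(both["chick_x_final"], both["adult_x_final"])))
    y = wide.dropna(subset=["chick_y80", "adult_y80"])
    if len(y) < 3:
        raise ValueError("fewer than 3 complete y80 pairs")
    icc_y = icc_oneway(list(zip(y["chick_y80"], y["adult_y80"])))
    return Q1Result(
        icc_x_final=icc_x,
        icc_y80=icc_y,
        metrics=wide.reset_index(),
        n_pairs_x_final=len(both),
        n_pairs_y80=len(y),
    )


def run_q2(chick_metrics: pd.DataFrame, mean_elo: Mapping[str, float]) -> Q2Result:
    """Chick metric vs adult mean Elo-rating rank correlations.

    ``chick_metrics`` needs columns individual, x_final, y80.
    """
    tbl = chick_metrics.copy()
    tbl["mean_elo"] = tbl["individual"].map(dict(mean_elo))
    tbl = tbl.dropna(subset=["mean_elo"])
    if len(tbl) < 3:
        raise ValueError("fewer than 3 individuals with both metric and rating")
    sp_x = spearman(tbl["x_final"], tbl["mean_elo"])
    y_tbl = tbl.dropna(subset=["y80"])
    sp_y = spearman(y_tbl["y80"], y_tbl["mean_elo"])
    return Q2Result(spearman_x_final=sp_x, spearman_y80=sp_y, table=tbl)


def run_q3(
    adult_trials: pd.DataFrame,
    mean_elo: Mapping[str, float],
    n_females: Mapping[str, int],
    cohort: Mapping[str, str],
    observations: pd.DataFrame | None = None,
    quad_points: int = 15,
) -> Q3Result:
    """GLMM of trial-level adult learning plus the manipulation check."""
    data = glmm.build_study_design(adult_trials, mean_elo, n_females, cohort)
    full = glmm.fit_binomial_glmm(data, quad_points=quad_points)
    lrts = glmm.drop_term_lrts(data, quad_points=quad_points, full_fit=full)
    minimal, _, history = glmm.minimum_adequate_model(data, quad_points=quad_points)
    rs = glmm.compare_random_structures(data, quad_points=quad_points)
    manipulation = None
    if observations is not None:
        summary = displays.rate_summary(observations)
        manipulation = {
            b: displays.condition_contrast(summary, b)
            for b in summary["behaviour"].unique()
        }
    return Q3Result(
        full_fit=full,
        full_lrts=lrts,
        minimal_fit=minimal,
        elimination=history,
        random_structure=rs,
        manipulation=manipulation,
    )


# ---------------------------------------------------------------------------
# synthetic end-to-end run


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:12]


def simulate_study(config: RunConfig) -> dict:
    """Generate a full synthetic cohort shaped like the captive study.

    12 males, ~1,000 interactions under a steep hierarchy; 30 chick and
    100 adult trials per male with chick→adult parameter correlation and
    a rank–slope coupling; Poisson display counts higher in PD.
    """
    seed = config.seed
    interactions, h_truth = synthetic.simulate_interactions(
        n_individuals=12, n_interactions=1044, steepness=2.0, seed=seed
    )
    ids = list(h_truth.abilities)
    chick_truth = synthetic.sample_learning_truth(ids, seed=seed + 1)
    adult_truth = synthetic.rank_coupled_truth(h_truth, coupling=0.03, seed=seed + 2)
    chick_trials = synthetic.simulate_trials(chick_truth, 30, seed=seed + 3, phase="chick")
    adult_trials = synthetic.simulate_trials(adult_truth, 100, seed=seed + 4, phase="adult")
    rng = np.random.default_rng(seed + 5)
    rates = {}
    for ind in ids:
        base_crow = rng.gamma(2.0, 1.5)
        base_strut = rng.gamma(2.0, 0.05)
        rates[(ind, "crow", "SG")] = base_crow
        rates[(ind, "crow", "PD")] = base_crow * 2.0
        rates[(ind, "lateral_strut", "SG")] = base_strut
        rates[(ind, "lateral_strut", "PD")] = base_strut * 2.0
    r_truth = synthetic.RateTruth(rates=rates)
    observations = synthetic.simulate_display_counts(r_truth, hours_per_condition=20.0, seed=seed + 6)
    females = {ind: (2 if i % 2 == 0 else 4) for i, ind in enumerate(ids)}
    cohort = {ind: ("I" if i < 6 else "II") for i, ind in enumerate(ids)}
    return {
        "interactions": interactions,
        "hierarchy_truth": h_truth,
        "chick_truth": chick_truth,
        "adult_truth": adult_truth,
        "chick_trials": chick_trials,
        "adult_trials": adult_trials,
        "rate_truth": r_truth,
        "observations": observations,
        "females": females,
        "cohort": cohort,
    }


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full synthetic pipeline: simulate, infer, analyse, report.

    Returns a report dict; when ``out_dir`` is given, every stage table
    is written there as CSV plus a ``report.json``.
    """
    study = simulate_study(config)
    elo_cfg = EloConfig(
        k_factor=config.elo_k,
        initial_rating=config.elo_initial,
        scale=config.elo_scale,
        n_randomizations=config.elo_n_randomizations,
        n_splits=config.elo_n_splits,
        seed=config.seed,
    )
    est = estimate_hierarchy(study["interactions"], elo_cfg)
    q1 = run_q1(study["chick_trials"], study["adult_trials"], window=config.learning_window)
    chick_metrics = learning.fit_cohort(study["chick_trials"], window=config.learning_window)
    q2 = run_q2(chick_metrics[["individual", "x_final", "y80"]], est.mean_elo)
    q3 = run_q3(
        study["adult_trials"],
        est.mean_elo,
        study["females"],
        study["cohort"],
        observations=study["observations"],
        quad_points=config.glmm_quad_points,
    )
    report = {
        "provenance": {
            "seed": config.seed,
            "config": config.to_dict(),
            "input_digests": {
                "interactions": _digest(study["interactions"]),
                "chick_trials": _digest(study["chick_trials"]),
                "adult_trials": _digest(study["adult_trials"]),
                "observations": _digest(study["observations"]),
            },
        },
        "hierarchy": {
            "repeatability_r": est.repeatability_r,
            "splithalf_mean": est.splithalf_mean,
            "splithalf_q025": est.splithalf_q025,
            "splithalf_q975": est.splithalf_q975,
            "n_interactions": est.n_interactions,
            "n_individuals": est.n_individuals,
        },
        "q1": {
            "icc_x_final": dataclasses.asdict(q1.icc_x_final),
            "icc_y80": dataclasses.asdict(q1.icc_y80),
        },
        "q2": {
            "spearman_x_final": dataclasses.asdict(q2.spearman_x_final),
            "spearman_y80": dataclasses.asdict(q2.spearman_y80),
        },
        "q3": {
            "full_loglik": q3.full_fit.loglik,
            "minimal_terms": list(q3.minimal_fit.term_map),
            "lrts": q3.full_lrts.to_dict(orient="records"),
            "random_structure": dataclasses.asdict(q3.random_structure),
            "manipulation": {
                b: {
                    "p": c.test.p,
                    "method": c.test.method,
                    "n_positive": c.n_positive,
                    "n_zero": c.n_zero,
                    "n_negative": c.n_negative,
                }
                for b, c in (q3.manipulation or {}).items()
            },
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        study["interactions"].to_csv(out / "interactions.csv", index=False)
        study["chick_trials"].to_csv(out / "chick_trials.csv", index=False)
        study["adult_trials"].to_csv(out / "adult_trials.csv", index=False)
        study["observations"].to_csv(out / "observations.csv", index=False)
        est.rank_table().to_csv(out / "hierarchy.csv", index=False)
        q1.metrics.to_csv(out / "q1_metrics.csv", index=False)
        q2.table.to_csv(out / "q2_table.csv", index=False)
        q3.full_fit.fixed_effects_table().to_csv(out / "q3_full_model.csv")
        q3.minimal_fit.fixed_effects_table().to_csv(out / "q3_minimal_model.csv")
        q3.full_lrts.to_csv(out / "q3_lrts.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
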