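"""Per-individual logistic learning curves and derived metrics.

Each individual's trial-level correct/incorrect sequence is fitted with
a two-parameter logistic regression of outcome on 1-based trial index,

    P(correct at trial t) = 1 / (1 + exp(-(b0 + b1 * t))),

over a fixed analysis window (default: first 20 trials, so chick and
adult curves are comparable). Two summary metrics follow:

* ``x_final`` — the fitted probability of a correct choice on the last
  trial of the window (accuracy at end of testing);
* ``y80`` — the trial index at which the fitted curve reaches an 80%
  probability of a correct choice, ``(-ln 0.25 - b0) / b1`` (speed of
  learning); undefined when the slope is zero, and possibly negative
  (criterion already met before trial 1) or beyond the window.

Small binary samples frequently exhibit complete separation (e.g. an
all-correct sequence), under which unbounded ML coefficients diverge.
Fits are therefore maximised under a coefficient cap |b| <= 15 and
flagged ``separated`` when the cap binds; metrics from capped fits are
computed but should be interpreted through the flag.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

#: -ln 0.25: the logit of the 80% learning criterion
LN4 = math.log(4.0)

#: coefficient cap applied under separation
COEF_BOUND = 15.0


@dataclasses.dataclass
class LearningCurveFit:
    individual: str
    phase: str
    b0: float
    b1: float
    n_trials_used: int
    converged: bool
    separated: bool


@dataclasses.dataclass
class LearningMetrics:
    x_final: float
    y80: float  # NaN when undefined
    y80_defined: bool
    final_trial: int


def _negloglik(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    eta = params[0] + params[1] * t
    # log(1+exp) stable form
    return float(np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta))


def fit_learning_curve(
    trials: pd.DataFrame,
    window: int = 20,
    bound: float = COEF_BOUND,
) -> LearningCurveFit:
    """Bounded-ML logistic regression of ``correct`` on trial index.

    ``trials`` must hold one (individual, phase); only trials with index
    <= ``window`` enter the fit.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    individuals = trials["individual"].unique()
    phases = trials["phase"].unique()
    if len(individuals) != 1 or len(phases) != 1:
        raise ValueError("fit_learning_curve expects one (individual, phase)")
    sub = trials[trials["trial"] <= window]
    if len(sub) < 2:
        raise ValueError("fewer than 2 trials inside the window")
    t = sub["trial"].to_numpy(float)
    y = sub["correct"].to_numpy(float)

    res = minimize(
        _negloglik,
        x0=np.zeros(2),
        args=(t, y),
        method="L-BFGS-B",
        bounds=[(-bound, bound), (-bound, bound)],
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    b0, b1 = res.x
    at_cap = max(abs(b0), abs(b1)) >= bound - 1e-6
    all_same = y.min() == y.max()
    separated = bool(at_cap or all_same)
    return LearningCurveFit(
        individual=str(individuals[0]),
        phase=str(phases[0]),
        b0=float(b0),
        b1=float(b1),
        n_trials_used=len(sub),
        converged=bool(res.success),
        separated=separated,
    )


def predict_correct_probability(fit: LearningCurveFit, trial: float) -> float:
    """Fitted probability of a correct choice at the given trial index."""
    return float(expit(fit.b0 + fit.b1 * trial))


def trials_to_criterion(fit: LearningCurveFit) -> float:
    """Trial index at which the fitted curve reaches the 80% criterion.

    Returns NaN when the slope is exactly zero (flat curve never crosses
    the criterion); negative values are reported as-is.
    """
    if fit.b1 == 0.0:
        return float("nan")
    return float((LN4 - fit.b0) / fit.b1)


def learning_metrics(fit: LearningCurveFit, final_trial: int | None = None) -> LearningMetrics:
    """Both derived metrics from one fitted curve.

    ``final_trial`` defaults to the number of trials used, i.e. the last
    index of the analysis window.
    """
    ft = fit.n_trials_used if final_trial is None else final_trial
    y80 = trials_to_criterion(fit)
    return LearningMetrics(
        x_final=predict_correct_probability(fit, ft),
        y80=y80,
        y80_defined=not math.isnan(y80),
        final_trial=ft,
    )


def fit_cohort(trials: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    """Fit every (individual, phase) in a trial table; tidy output.

    Columns: individual, phase, b0, b1, n_trials_used, converged,
    separated, x_final, y80, y80_defined, final_trial.
    """
    rows = []
    for (ind, phase), grp in trials.groupby(["individual", "phase"], sort=True):
        fit = fit_learning_curve(grp, window=window)
        m = learning_metrics(fit)
        rows.append(
            {
                "individual": ind,
                "phase": phase,
                "b0": fit.b0,
                "b1": fit.b1,
                "n_trials_used": fit.n_trials_used,
                "converged": fit.converged,
                "separated": fit.separated,
                "x_final": m.x_final,
                "y80": m.y80,
                "y80_defined": m.y80_defined,
                "final_trial": m.final_trial,
            }
        )
    return pd.DataFrame(rows)
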