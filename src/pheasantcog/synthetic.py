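"""Synthetic cohorts with known ground truth.

Three generators emulate the data shapes of a captive pheasant cohort:

* winner–loser agonistic interactions under a steepness-parameterised
  latent hierarchy (win probability logistic in ability difference),
* per-individual binary learning trials from logistic learning curves,
* Poisson dominance-display counts in two housing conditions.

Every generator is deterministic under its seed and emits a *truth*
object alongside the dataset so downstream estimators can be checked
against known parameters without re-deriving them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .io_formats import BEHAVIOURS, CONDITIONS


@dataclasses.dataclass
class HierarchyTruth:
    """Latent abilities behind a simulated hierarchy.

    ``P(i beats j) = expit(steepness * (ability_i - ability_j))``; at
    steepness 0 every contest is a coin flip, and larger steepness makes
    the hierarchy more despotic (more predictable contest outcomes).
    """

    abilities: dict[str, float]
    steepness: float

    def win_probability(self, winner: str, loser: str) -> float:
        from scipy.special import expit

        return float(
            expit(self.steepness * (self.abilities[winner] - self.abilities[loser]))
        )


@dataclasses.dataclass
class LearningTruth:
    """Per-individual true logistic learning-curve parameters.

    The probability of a correct choice at 1-based trial ``t`` is
    ``expit(b0 + b1 * t)``.
    """

    b0: dict[str, float]
    b1: dict[str, float]


@dataclasses.dataclass
class RateTruth:
    """True hourly display rates keyed by (individual, behaviour, condition)."""

    rates: dict[tuple[str, str, str], float]


def _default_ids(n: int, prefix: str = "M") -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def default_abilities(n_individuals: int) -> dict[str, float]:
    """Evenly spaced latent abilities, centred, unit sample SD."""
    a = np.linspace(1.0, -1.0, n_individuals)
    a = a / a.std(ddof=1)
    return dict(zip(_default_ids(n_individuals), a))


def simulate_interactions(
    n_individuals: int,
    n_interactions: int,
    steepness: float,
    pairing: Literal["uniform", "rank-biased"] = "uniform",
    seed: int = 0,
    abilities: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, HierarchyTruth]:
    """Simulate a winner–loser interaction dataset.

    Dyads are drawn either uniformly or with weight decaying geometrically
    in rank distance (real sparring concentrates among rank neighbours);
    within a drawn dyad the winner is sampled from the logistic win model.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if n_interactions < 1:
        raise ValueError("need at least 1 interaction")
    if abilities is None:
        abilities = default_abilities(n_individuals)
    elif len(abilities) != n_individuals:
        raise ValueError("abilities must cover every individual")
    ids = list(abilities)
    a = np.array([abilities[i] for i in ids])
    rng = np.random.default_rng(seed)

    pairs = [(i, j) for i in range(n_individuals) for j in range(i + 1, n_individuals)]
    pairs = np.array(pairs)
    if pairing == "uniform":
        w = np.ones(len(pairs))
    elif pairing == "rank-biased":
        order = np.argsort(-a)  # rank 0 = highest ability
        rank = np.empty(n_individuals, int)
        rank[order] = np.arange(n_individuals)
        dist = np.abs(rank[pairs[:, 0]] - rank[pairs[:, 1]])
        w = 0.5 ** (dist - 1)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    w = w / w.sum()

    from scipy.special import expit

    choice = rng.choice(len(pairs), size=n_interactions, p=w)
    i_idx = pairs[choice, 0]
    j_idx = pairs[choice, 1]
    p_i_wins = expit(steepness * (a[i_idx] - a[j_idx]))
    i_wins = rng.random(n_interactions) < p_i_wins
    win = np.where(i_wins, i_idx, j_idx)
    lose = np.where(i_wins, j_idx, i_idx)
    df = pd.DataFrame(
        {
            "winner": [ids[k] for k in win],
            "loser": [ids[k] for k in lose],
            "order": np.arange(n_interactions),
        }
    )
    return df, HierarchyTruth(abilities=dict(abilities), steepness=steepness)


def sample_learning_truth(
    ids: list[str],
    seed: int = 0,
    b0_mean: float = -0.7,
    b0_sd: float = 0.6,
    b1_mean: float = 0.10,
    b1_sd: float = 0.05,
) -> LearningTruth:
    """Draw individual learning-curve parameters from a population.

    Defaults describe birds starting slightly below chance-corrected
    competence (expit(-0.7) ~ 0.33 at trial 0) and reaching ~80% correct
    within roughly 20 trials at the mean slope — the regime of a cohort
    that learns a two-choice spatial discrimination within a session
    block.
    """
    rng = np.random.default_rng(seed)
    b0 = rng.normal(b0_mean, b0_sd, len(ids))
    b1 = rng.normal(b1_mean, b1_sd, len(ids))
    return LearningTruth(b0=dict(zip(ids, b0)), b1=dict(zip(ids, b1)))


def correlated_adult_truth(
    chick: LearningTruth,
    correlation: float,
    seed: int = 0,
    b0_sd: float = 0.6,
    b1_sd: float = 0.05,
) -> LearningTruth:
    """Adult-phase parameters correlated with chick-phase parameters.

    ``correlation`` is applied to both intercept and slope around their
    chick-cohort means; 1 duplicates the chick parameters, 0 makes the
    phases independent.
    """
    rng = np.random.default_rng(seed)
    ids = list(chick.b0)
    c0 = np.array([chick.b0[i] for i in ids])
    c1 = np.array([chick.b1[i] for i in ids])
    r = correlation
    a0 = c0.mean() + r * (c0 - c0.mean()) + np.sqrt(max(0.0, 1 - r**2)) * rng.normal(0, b0_sd, len(ids))
    a1 = c1.mean() + r * (c1 - c1.mean()) + np.sqrt(max(0.0, 1 - r**2)) * rng.normal(0, b1_sd, len(ids))
    return LearningTruth(b0=dict(zip(ids, a0)), b1=dict(zip(ids, a1)))


def rank_coupled_truth(
    hierarchy: HierarchyTruth,
    coupling: float,
    seed: int = 0,
    b0_mean: float = 0.5,
    b0_sd: float = 0.3,
    b1_mean: float = 0.03,
    b1_sd: float = 0.01,
) -> LearningTruth:
    """Learning slopes coupled to latent ability (rank–slope coupling).

    ``b1_i = b1_mean + coupling * ability_i + noise`` so higher-ranked
    individuals learn faster when ``coupling > 0``.
    """
    rng = np.random.default_rng(seed)
    ids = list(hierarchy.abilities)
    a = np.array([hierarchy.abilities[i] for i in ids])
    b0 = rng.normal(b0_mean, b0_sd, len(ids))
    b1 = b1_mean + coupling * a + rng.normal(0, b1_sd, len(ids))
    return LearningTruth(b0=dict(zip(ids, b0)), b1=dict(zip(ids, b1)))


def simulate_trials(
    truth: LearningTruth,
    n_trials: int,
    seed: int = 0,
    phase: str = "adult",
) -> pd.DataFrame:
    """Bernoulli trial outcomes from each individual's logistic curve."""
    if n_trials < 1:
        raise ValueError("need at least 1 trial")
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    rows = []
    t = np.arange(1, n_trials + 1)
    for ind in truth.b0:
        p = expit(truth.b0[ind] + truth.b1[ind] * t)
        y = (rng.random(n_trials) < p).astype(int)
        rows.append(
            pd.DataFrame({"individual": ind, "phase": phase, "trial": t, "correct": y})
        )
    return pd.concat(rows, ignore_index=True)


def simulate_display_counts(
    truth: RateTruth,
    hours_per_condition: float,
    seed: int = 0,
    n_females: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Poisson display counts: events ~ Poisson(rate × hours).

    ``n_females`` maps (individual, condition) to the housed female count;
    defaults to 19 in SG and 2 in PD.
    """
    if hours_per_condition <= 0:
        raise ValueError("hours must be positive")
    if any(r < 0 for r in truth.rates.values()):
        raise ValueError("negative rate in truth")
    rng = np.random.default_rng(seed)
    rows = []
    for (ind, behaviour, condition), rate in sorted(truth.rates.items()):
        if behaviour not in BEHAVIOURS or condition not in CONDITIONS:
            raise ValueError(f"bad truth key {(ind, behaviour, condition)}")
        nf = 19 if condition == "SG" else 2
        if n_females is not None:
            nf = n_females.get((ind, condition), nf)
        rows.append(
            {
                "individual": ind,
                "condition": condition,
                "behaviour": behaviour,
                "events": int(rng.poisson(rate * hours_per_condition)),
                "hours": hours_per_condition,
                "n_females": nf,
                "directed": "female",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth sidecars


def save_truth(truth, path: str | Path) -> None:
    """Serialise a truth object to a YAML sidecar next to its dataset."""
    if isinstance(truth, HierarchyTruth):
        payload = {
            "kind": "hierarchy",
            "steepness": float(truth.steepness),
            "abilities": {k: float(v) for k, v in truth.abilities.items()},
        }
    elif isinstance(truth, LearningTruth):
        payload = {
            "kind": "learning",
            "b0": {k: float(v) for k, v in truth.b0.items()},
            "b1": {k: float(v) for k, v in truth.b1.items()},
        }
    elif isinstance(truth, RateTruth):
        payload = {
            "kind": "rates",
            "rates": [
                {"individual": i, "behaviour": b, "condition": c, "rate": float(r)}
                for (i, b, c), r in sorted(truth.rates.items())
            ],
        }
    else:
        raise TypeError(f"unknown truth type {type(truth)!r}")
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_truth(path: str | Path):
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kind = payload.get("kind")
    if kind == "hierarchy":
        return HierarchyTruth(abilities=payload["abilities"], steepness=payload["steepness"])
    if kind == "learning":
        return LearningTruth(b0=payload["b0"], b1=payload["b1"])
    if kind == "rates":
        return RateTruth(
            rates={
                (r["individual"], r["behaviour"], r["condition"]): r["rate"]
                for r in payload["rates"]
            }
        )
    raise ValueError(f"unknown truth kind {kind!r}")
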