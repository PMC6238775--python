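"""Randomized Elo-rating hierarchy inference with uncertainty diagnostics.

Social rank is inferred from winner–loser interaction records by Elo
scoring, with the sequential dependence on observation order removed by
averaging ratings over many random re-orderings of the interaction
sequence ("randomized Elo-ratings"). Hierarchy certainty is quantified
two ways:

* **repeatability** — the among-individual share of rating variance
  across replicate orderings (one-way variance components); high values
  mean a steep, well-resolved hierarchy;
* **split-half reliability** — Spearman correlation between mean ratings
  inferred independently from two random halves of the dataset, repeated
  over many splits and summarised by its mean and 2.5%/97.5% quantiles.

The Elo update constants (k-factor, initial rating, expected-score
scale) are conventions rather than estimated quantities; defaults are
recorded in every :class:`HierarchyEstimate` so results are traceable.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr


@dataclasses.dataclass
class EloConfig:
    """Constants of the Elo engine and its randomization diagnostics."""

    k_factor: float = 200.0
    initial_rating: float = 0.0
    #: scale of the logistic expected-score curve, in rating points
    scale: float = 200.0
    n_randomizations: int = 1000
    n_splits: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_factor <= 0:
            raise ValueError("k_factor must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclasses.dataclass
class HierarchyEstimate:
    """Mean randomized Elo-ratings plus reliability diagnostics."""

    mean_elo: dict[str, float]
    repeatability_r: float
    splithalf_mean: float
    splithalf_q025: float
    splithalf_q975: float
    n_interactions: int
    n_individuals: int
    config: EloConfig

    def rank_table(self) -> pd.DataFrame:
        """Tidy table: id, mean Elo, dense rank (1 = highest rating)."""
        s = pd.Series(self.mean_elo).sort_values(ascending=False)
        return pd.DataFrame(
            {"individual": s.index, "mean_elo": s.values, "rank": np.arange(1, len(s) + 1)}
        )


def _roster(records: pd.DataFrame) -> list[str]:
    return sorted(set(records["winner"]) | set(records["loser"]))


def elo_sequence(
    records: pd.DataFrame,
    config: EloConfig,
    roster: list[str] | None = None,
) -> dict[str, float]:
    """Score one ordering of the interaction sequence.

    The winner's expected score is logistic in the current rating
    difference; the winner gains ``k * (1 - expected)`` and the loser
    loses the same amount, so the rating sum is conserved exactly.
    """
    if len(records) == 0:
        raise ValueError("empty interaction record list")
    ids = roster if roster is not None else _roster(records)
    rating = {i: float(config.initial_rating) for i in ids}
    order = records.sort_values("order") if "order" in records.columns else records
    for w, l in zip(order["winner"], order["loser"]):
        expected = expit((rating[w] - rating[l]) / config.scale)
        delta = config.k_factor * (1.0 - expected)
        rating[w] += delta
        rating[l] -= delta
    return rating


def _randomized_ratings_matrix(
    winner_idx: np.ndarray,
    loser_idx: np.ndarray,
    n_individuals: int,
    config: EloConfig,
    rng: np.random.Generator,
    n_randomizations: int,
) -> np.ndarray:
    """Elo over many random orderings at once (replicates × individuals)."""
    n_rec = len(winner_idx)
    # each row of `perm` is an independent uniform permutation of record order
    perm = np.argsort(rng.random((n_randomizations, n_rec)), axis=1)
    W = winner_idx[perm]
    L = loser_idx[perm]
    ratings = np.full((n_randomizations, n_individuals), config.initial_rating, float)
    rows = np.arange(n_randomizations)
    for t in range(n_rec):
        wi = W[:, t]
        li = L[:, t]
        rw = ratings[rows, wi]
        rl = ratings[rows, li]
        delta = config.k_factor * (1.0 - expit((rw - rl) / config.scale))
        ratings[rows, wi] = rw + delta
        ratings[rows, li] = rl - delta
    return ratings


def randomized_elo(
    records: pd.DataFrame,
    config: EloConfig,
    roster: list[str] | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Randomized Elo-ratings.

    Returns the replicate matrix (one row per random ordering, one column
    per individual) and the per-individual column means ("mean
    Elo-rating"), reproducible under ``config.seed``.
    """
    if len(records) == 0:
        raise ValueError("empty interaction record list")
    ids = roster if roster is not None else _roster(records)
    idx = {v: k for k, v in enumerate(ids)}
    w = records["winner"].map(idx).to_numpy()
    l = records["loser"].map(idx).to_numpy()
    rng = np.random.default_rng(config.seed)
    matrix = _randomized_ratings_matrix(w, l, len(ids), config, rng, config.n_randomizations)
    mean_elo = pd.Series(matrix.mean(axis=0), index=ids, name="mean_elo")
    return matrix, mean_elo


def elo_repeatability(matrix: np.ndarray) -> float:
    """Among-individual variance share across replicate orderings.

    One-way variance-components decomposition with individuals as groups
    and replicate orderings as repeats:
    ``r = sigma2_among / (sigma2_among + sigma2_within)`` from ANOVA mean
    squares. Reported raw (may be negative); NaN when total variance is
    zero.
    """
    matrix = np.asarray(matrix, float)
    n_rep, n_ind = matrix.shape
    if n_rep < 2 or n_ind < 2:
        raise ValueError("need >= 2 replicates and >= 2 individuals")
    col_means = matrix.mean(axis=0)
    grand = matrix.mean()
    ms_among = n_rep * np.sum((col_means - grand) ** 2) / (n_ind - 1)
    ms_within = np.sum((matrix - col_means) ** 2) / (n_ind * (n_rep - 1))
    if ms_among == 0.0 and ms_within == 0.0:
        return float("nan")
    sigma2_among = (ms_among - ms_within) / n_rep
    return float(sigma2_among / (sigma2_among + ms_within))


def split_half_reliability(
    records: pd.DataFrame,
    config: EloConfig,
    roster: list[str] | None = None,
) -> tuple[float, float, float]:
    """Split-half reliability of the inferred hierarchy.

    For each of ``config.n_splits`` uniformly random partitions of the
    interaction records into two near-equal halves, mean randomized Elo
    is computed per half and the two rating vectors are Spearman
    correlated over the individuals present in both halves. Splits
    sharing fewer than 3 individuals are skipped with a warning. Returns
    the mean and the 2.5%/97.5% quantiles of the correlations.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 interactions to split")
    ids = roster if roster is not None else _roster(records)
    idx = {v: k for k, v in enumerate(ids)}
    w = records["winner"].map(idx).to_numpy()
    l = records["loser"].map(idx).to_numpy()
    n_rec = len(records)
    rng = np.random.default_rng(config.seed)
    half = n_rec // 2
    corrs: list[float] = []
    for _ in range(config.n_splits):
        perm = rng.permutation(n_rec)
        first, second = perm[:half], perm[half:]
        means = []
        present = []
        for part in (first, second):
            m = _randomized_ratings_matrix(
                w[part], l[part], len(ids), config, rng, config.n_randomizations
            )
            means.append(m.mean(axis=0))
            present.append(np.zeros(len(ids), bool))
            present[-1][np.concatenate([w[part], l[part]])] = True
        shared = present[0] & present[1]
        if shared.sum() < 3:
            warnings.warn("split shares fewer than 3 individuals; skipped")
            continue
        rho = spearmanr(means[0][shared], means[1][shared]).statistic
        corrs.append(float(rho))
    if not corrs:
        raise ValueError("no usable splits (too few shared individuals)")
    arr = np.array(corrs)
    return (
        float(arr.mean()),
        float(np.quantile(arr, 0.025)),
        float(np.quantile(arr, 0.975)),
    )


def estimate_hierarchy(
    records: pd.DataFrame,
    config: EloConfig | None = None,
    roster: list[str] | None = None,
) -> HierarchyEstimate:
    """Full hierarchy inference: mean Elo + both certainty diagnostics."""
    config = config or EloConfig()
    ids = roster if roster is not None else _roster(records)
    matrix, mean_elo = randomized_elo(records, config, roster=ids)
    r = elo_repeatability(matrix)
    sh_mean, sh_lo, sh_hi = split_half_reliability(records, config, roster=ids)
    return HierarchyEstimate(
        mean_elo=mean_elo.to_dict(),
        repeatability_r=r,
        splithalf_mean=sh_mean,
        splithalf_q025=sh_lo,
        splithalf_q975=sh_hi,
        n_interactions=len(records),
        n_individuals=len(ids),
        config=config,
    )
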