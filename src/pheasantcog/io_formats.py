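"""Tabular input/output and run configuration.

All record types travel as comma-separated UTF-8 files with a mandatory
header row and come back as validated :class:`pandas.DataFrame` objects.
Identifiers are opaque strings (wing-tag labels); no numeric meaning is
assumed. Where an interaction file carries no ``order`` column, file row
order defines the observation sequence.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

PHASES = ("chick", "adult")
CONDITIONS = ("SG", "PD")
BEHAVIOURS = ("crow", "lateral_strut")
DIRECTIONS = ("female", "male", "ambiguous")

#: maximum trials per life phase (three 10-trial chick sessions; five
#: 20-trial adult sessions)
MAX_TRIALS = {"chick": 30, "adult": 100}


class ValidationError(ValueError):
    """A file violated the documented schema; the message names the row."""


# ---------------------------------------------------------------------------
# interactions


def read_interactions(path: str | Path, roster: Sequence[str] | None = None) -> pd.DataFrame:
    """Read winner–loser agonistic interaction records.

    Parameters
    ----------
    path
        CSV with columns ``winner``, ``loser`` and optionally ``order``.
    roster
        Declared set of individual ids; rows naming an id outside the
        roster raise :class:`ValidationError`.

    Returns
    -------
    DataFrame with columns ``winner, loser, order`` sorted by ``order``.
    """
    df = pd.read_csv(path, dtype={"winner": str, "loser": str})
    return validate_interactions(df, roster=roster)


def validate_interactions(df: pd.DataFrame, roster: Sequence[str] | None = None) -> pd.DataFrame:
    for col in ("winner", "loser"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    df = df.copy()
    df["winner"] = df["winner"].astype(str)
    df["loser"] = df["loser"].astype(str)
    if "order" not in df.columns:
        df["order"] = range(len(df))
    if df["order"].duplicated().any():
        row = int(df.index[df["order"].duplicated()][0])
        raise ValidationError(f"duplicate order value at row {row}")
    if (df["order"] < 0).any():
        row = int(df.index[df["order"] < 0][0])
        raise ValidationError(f"negative order at row {row}")
    same = df["winner"] == df["loser"]
    if same.any():
        row = int(df.index[same][0])
        raise ValidationError(f"winner equals loser at row {row}")
    if roster is not None:
        known = set(map(str, roster))
        for col in ("winner", "loser"):
            bad = ~df[col].isin(known)
            if bad.any():
                row = int(df.index[bad][0])
                raise ValidationError(
                    f"unknown id {df.loc[row, col]!r} in column {col!r} at row {row}"
                )
    return df.sort_values("order", kind="stable").reset_index(drop=True)


def write_interactions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=["winner", "loser", "order"])


# ---------------------------------------------------------------------------
# trials


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read binary cognitive-test trials (individual, phase, trial, correct)."""
    df = pd.read_csv(path, dtype={"individual": str})
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("individual", "phase", "trial", "correct"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    df = df.copy()
    df["individual"] = df["individual"].astype(str)
    df["phase"] = df["phase"].astype(str).str.lower()
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        row = int(df.index[bad_phase][0])
        raise ValidationError(f"unknown phase {df.loc[row, 'phase']!r} at row {row}")
    if not df["correct"].isin((0, 1)).all():
        row = int(df.index[~df["correct"].isin((0, 1))][0])
        raise ValidationError(f"correct outside {{0,1}} at row {row}")
    df["trial"] = df["trial"].astype(int)
    df["correct"] = df["correct"].astype(int)
    for (ind, phase), grp in df.groupby(["individual", "phase"], sort=False):
        t = sorted(grp["trial"])
        if t != list(range(1, len(t) + 1)):
            raise ValidationError(
                f"trials for ({ind}, {phase}) are not consecutive from 1: {t[:5]}..."
            )
        if len(t) > MAX_TRIALS[phase]:
            raise ValidationError(
                f"({ind}, {phase}) has {len(t)} trials; phase maximum is {MAX_TRIALS[phase]}"
            )
    return (
        df.sort_values(["individual", "phase", "trial"], kind="stable").reset_index(drop=True)
    )


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=["individual", "phase", "trial", "correct"])


# ---------------------------------------------------------------------------
# display observations


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read dominance-display observation records.

    Columns: ``individual, condition, behaviour, events, hours, n_females``
    and optionally ``directed`` (female/male/ambiguous; assumed female when
    absent — only female-directed lateral struts enter analysis).
    """
    df = pd.read_csv(path, dtype={"individual": str})
    return validate_observations(df)


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    required = ("individual", "condition", "behaviour", "events", "hours", "n_females")
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    df = df.copy()
    df["individual"] = df["individual"].astype(str)
    df["condition"] = df["condition"].astype(str).str.upper()
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(f"unknown condition {df.loc[row, 'condition']!r} at row {row}")
    df["behaviour"] = df["behaviour"].astype(str).str.lower()
    bad = ~df["behaviour"].isin(BEHAVIOURS)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(f"unknown behaviour {df.loc[row, 'behaviour']!r} at row {row}")
    if (df["events"] < 0).any():
        row = int(df.index[df["events"] < 0][0])
        raise ValidationError(f"negative event count at row {row}")
    if (df["hours"] <= 0).any():
        row = int(df.index[df["hours"] <= 0][0])
        raise ValidationError(f"non-positive hours at row {row}")
    if (df["n_females"] < 1).any():
        row = int(df.index[df["n_females"] < 1][0])
        raise ValidationError(f"n_females < 1 at row {row}")
    if "directed" not in df.columns:
        df["directed"] = "female"
    df["directed"] = df["directed"].astype(str).str.lower()
    bad = ~df["directed"].isin(DIRECTIONS)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(f"unknown direction {df.loc[row, 'directed']!r} at row {row}")
    return df.reset_index(drop=True)


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["individual", "condition", "behaviour", "events", "hours", "n_females"]
    if "directed" in df.columns:
        cols.append("directed")
    df.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """All tunables of a full pipeline run, explicit after load."""

    seed: int = 0
    # Elo settings (constants unstated in the source study; recorded in output)
    elo_k: float = 200.0
    elo_initial: float = 0.0
    elo_scale: float = 200.0
    elo_n_randomizations: int = 1000
    elo_n_splits: int = 100
    # learning-curve window for chick/adult comparability
    learning_window: int = 20
    # GLMM quadrature order
    glmm_quad_points: int = 15
    # file paths (optional; used by the CLI)
    interactions_path: str | None = None
    chick_trials_path: str | None = None
    adult_trials_path: str | None = None
    observations_path: str | None = None
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
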