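"""Published summary tables of the pheasant rank/learning study.

These are the desk-scale inputs printed in the source article (PeerJ
7717/peerj.5738): the per-male display-rate table used for the
rank-manipulation check, the hierarchy diagnostics of the two cohorts,
and the per-male housing covariates. The per-individual raw datasets
(trial-level outcomes, chick/adult metric pairs) were deposited as
supplementary files and are *not* reproduced here; adapters for them
live in :func:`load_supplementary`.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

# Per-male display rates (events/hour) in the Social Group (SG) and
# Perceived Dominance (PD) conditions, with the male's mean Elo-rating
# and the number of females housed with him in PD. Lateral-strut rates
# are already adjusted for female density (19 females in SG; 2 or 4 in
# PD); crow rates are unadjusted. Ten males of cohort I.
_DISPLAY_RATES_CSV = """\
male,mean_elo,females,strut_sg,strut_pd,strut_increase,crow_sg,crow_pd,crow_increase
1,773.8359,2,0.138,0.1,-0.038,6.655,11.333,4.679
2,403.1283,4,0.01,0.017,0.007,0.036,4.3,4.263
3,385.0008,4,0.096,0.167,0.071,0.145,0.333,0.188
4,207.2864,2,0.013,0.017,0.003,0,3.467,3.367
5,-16.0075,2,0.019,0.017,-0.002,0,5.4,5.400
6,-140.793,4,0.025,0.225,0.2,0,0,0
7,-302.046,2,0.006,0.133,0.128,0,10.767,10.767
8,-421.245,2,0.057,0.017,-0.041,0,0,0
9,-601.546,4,0.002,0.15,0.148,0,3.233,3.233
10,-891.792,4,0.01,0.05,0.04,0,0.067,0.067
"""

# Hierarchy diagnostics per cohort: repeatability r of randomized
# Elo-ratings over 1,000 replicate orderings, and the mean / 2.5% / 97.5%
# split-half Spearman correlation.
_HIERARCHY_STATS_CSV = """\
cohort,n_males,n_interactions,obs_days,repeatability_r,splithalf_mean,splithalf_q025,splithalf_q975
I,12,1044,47,0.984,0.948,0.881,0.993
II,9,701,14,0.996,0.976,0.917,1.000
"""

# Housing covariates for the eight GLMM males: within-cohort social rank,
# number of females in PD, and first-trial choice.
_HOUSING_CSV = """\
cohort,rank,females,first_choice
II,2,4,0
II,3,4,1
II,4,2,0
II,5,2,1
II,6,4,0
I,7,4,1
I,10,2,0
I,12,2,1
"""


def load_display_rates() -> pd.DataFrame:
    """Per-male SG/PD display rates (struts female-density adjusted)."""
    return pd.read_csv(io.StringIO(_DISPLAY_RATES_CSV), dtype={"male": str})


def load_display_rate_summary() -> pd.DataFrame:
    """Display rates reshaped to the tidy per-behaviour contrast layout."""
    wide = load_display_rates()
    rows = []
    for behaviour, sg, pd_, adjusted in (
        ("crow", "crow_sg", "crow_pd", False),
        ("lateral_strut", "strut_sg", "strut_pd", True),
    ):
        part = wide[["male", sg, pd_]].rename(
            columns={"male": "individual", sg: "sg_rate", pd_: "pd_rate"}
        )
        part["behaviour"] = behaviour
        part["increase"] = part["pd_rate"] - part["sg_rate"]
        part["adjusted"] = adjusted
        rows.append(part)
    return pd.concat(rows, ignore_index=True)[
        ["individual", "behaviour", "sg_rate", "pd_rate", "increase", "adjusted"]
    ]


def load_hierarchy_stats() -> pd.DataFrame:
    """Published hierarchy certainty diagnostics for cohorts I and II."""
    return pd.read_csv(io.StringIO(_HIERARCHY_STATS_CSV))


def load_housing_covariates() -> pd.DataFrame:
    """Rank, female count and first choice for the eight modelled males."""
    return pd.read_csv(io.StringIO(_HOUSING_CSV))


# ---------------------------------------------------------------------------
# supplementary-file adapters

#: default column mapping from the deposited spreadsheets to the package
#: schemas; override entries when inspecting the actual files shows other
#: headers (their exact layout is not described in the article).
DEFAULT_SUPPLEMENTARY_MAP = {
    "q1_metrics": {  # chick & adult learning metrics, one row per individual
        "individual": "individual",
        "chick_x_final": "chick_x_final",
        "adult_x_final": "adult_x_final",
        "chick_y80": "chick_y80",
        "adult_y80": "adult_y80",
    },
    "q2_metrics": {  # chick metrics + adult mean Elo-rating
        "individual": "individual",
        "x_final": "x_final",
        "y80": "y80",
        "mean_elo": "mean_elo",
    },
    "q3_trials": {  # trial-level adult outcomes with covariates
        "individual": "individual",
        "trial": "trial",
        "correct": "correct",
        "mean_elo": "mean_elo",
        "females": "females",
        "cohort": "cohort",
    },
}


def load_supplementary(
    directory: str | Path,
    which: str,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a deposited supplementary dataset through a column mapping.

    ``directory`` holds CSV exports named ``q1_metrics.csv``,
    ``q2_metrics.csv``, ``q3_trials.csv``; ``column_map`` translates the
    file's actual headers to the package schema (keys = schema names,
    values = file headers).
    """
    if which not in DEFAULT_SUPPLEMENTARY_MAP:
        raise ValueError(f"unknown supplementary dataset {which!r}")
    path = Path(directory) / f"{which}.csv"
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary dataset {path} not found; deposit the published "
            "per-individual data there as CSV to run the reproduction"
        )
    mapping = dict(DEFAULT_SUPPLEMENTARY_MAP[which])
    if column_map:
        mapping.update(column_map)
    df = pd.read_csv(path)
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [k for k in mapping if k not in df.columns]
    if missing:
        raise ValueError(f"{path} lacks mapped columns {missing}")
    return df[list(mapping)]
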