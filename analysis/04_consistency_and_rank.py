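#!/usr/bin/env python
"""Question 1 and 2: chick→adult consistency and rank association.

Q1: one-way intraclass correlation between chick and adult learning
metrics on the common 20-trial window. Q2: Spearman correlation of each
chick metric against the adult mean Elo-rating. On the simulated
cohort the adult slopes are rank-coupled while the chick parameters are
rank-independent, so Q2 is expected near zero and Q1 reflects the
generator's chick→adult parameter correlation.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from pheasantcog import io_formats, learning, pipeline

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--hierarchy", type=Path, default=Path("results/hierarchy.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--window", type=int, default=20)
args = parser.parse_args()

chick = io_formats.read_trials(args.data / "chick_trials.csv")
adult = io_formats.read_trials(args.data / "adult_trials.csv")
hier = pd.read_csv(args.hierarchy, dtype={"individual": str})
mean_elo = dict(zip(hier["individual"], hier["mean_elo"]))

q1 = pipeline.run_q1(chick, adult, window=args.window)
chick_metrics = learning.fit_cohort(chick, window=args.window)[
    ["individual", "x_final", "y80"]
]
q2 = pipeline.run_q2(chick_metrics, mean_elo)

args.out.mkdir(parents=True, exist_ok=True)
q1.metrics.to_csv(args.out / "q1_metrics.csv", index=False)
rows = [
    {"question": "q1", "measure": "icc_x_final", **dataclasses.asdict(q1.icc_x_final)},
    {"question": "q1", "measure": "icc_y80", **dataclasses.asdict(q1.icc_y80)},
]
pd.DataFrame(rows).to_csv(args.out / "q1_icc.csv", index=False)
rows = [
    {"question": "q2", "measure": "x_final_vs_elo", **dataclasses.asdict(q2.spearman_x_final)},
    {"question": "q2", "measure": "y80_vs_elo", **dataclasses.asdict(q2.spearman_y80)},
]
pd.DataFrame(rows).to_csv(args.out / "q2_spearman.csv", index=False)

print(f"Q1 consistency ({q1.n_pairs_x_final} birds tested in both phases):")
print(f"  ICC(x_final) = {q1.icc_x_final.icc:.3f} "
      f"[{q1.icc_x_final.ci_low:.3f}, {q1.icc_x_final.ci_high:.3f}]")
print(f"  ICC(y80)     = {q1.icc_y80.icc:.3f} "
      f"[{q1.icc_y80.ci_low:.3f}, {q1.icc_y80.ci_high:.3f}]")
print(f"Q2 association (n = {q2.spearman_x_final.n}):")
print(f"  r_s(x_final, mean Elo) = {q2.spearman_x_final.r_s:.3f} "
      f"(p = {q2.spearman_x_final.p:.3f}, {q2.spearman_x_final.method})")
print(f"  r_s(y80, mean Elo)     = {q2.spearman_y80.r_s:.3f} "
      f"(p = {q2.spearman_y80.p:.3f}, {q2.spearman_y80.method})")
print(f"wrote q1_metrics.csv, q1_icc.csv, q2_spearman.csv to {args.out}")
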