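#!/usr/bin/env python
"""Generate the synthetic study cohorts used by the downstream analyses.

Emulates a captive pheasant cohort: 12 males exchanging ~1,000 dyadic
agonistic interactions under a steep latent hierarchy, 30 chick and 100
adult binary spatial-discrimination trials per male (adult learning
slopes coupled to latent rank), and Poisson dominance-display counts
that double from the social-group to the perceived-dominance condition.
Writes the datasets plus their ground-truth sidecars under
results/data/.
"""

import argparse
from pathlib import Path

from pheasantcog import io_formats, pipeline, synthetic

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = io_formats.RunConfig(seed=args.seed)
study = pipeline.simulate_study(cfg)

args.out.mkdir(parents=True, exist_ok=True)
io_formats.write_interactions(study["interactions"], args.out / "interactions.csv")
io_formats.write_trials(study["chick_trials"], args.out / "chick_trials.csv")
io_formats.write_trials(study["adult_trials"], args.out / "adult_trials.csv")
io_formats.write_observations(study["observations"], args.out / "observations.csv")
synthetic.save_truth(study["hierarchy_truth"], args.out / "hierarchy_truth.yaml")
synthetic.save_truth(study["chick_truth"], args.out / "chick_truth.yaml")
synthetic.save_truth(study["adult_truth"], args.out / "adult_truth.yaml")
synthetic.save_truth(study["rate_truth"], args.out / "rate_truth.yaml")
io_formats.save_config(cfg, args.out / "config.yaml")

print(f"simulated cohort (seed {args.seed}):")
print(f"  {study['interactions'].shape[0]} interactions among "
      f"{len(study['hierarchy_truth'].abilities)} males "
      f"(steepness {study['hierarchy_truth'].steepness})")
print(f"  {study['chick_trials']['individual'].nunique()} chicks x 30 trials, "
      f"{study['adult_trials']['individual'].nunique()} adults x 100 trials")
print(f"  {len(study['observations'])} display observation records")
print(f"wrote datasets and truth sidecars to {args.out}")
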