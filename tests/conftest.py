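import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def steep_cohort():
    """Cohort-sized interaction dataset under a steep latent hierarchy."""
    from pheasantcog import synthetic

    records, truth = synthetic.simulate_interactions(
        n_individuals=12, n_interactions=1044, steepness=2.0, seed=11
    )
    return records, truth


@pytest.fixture
def learner_trials():
    """Trials for a small cohort of genuine learners (positive slopes)."""
    from pheasantcog import synthetic

    ids = [f"b{k}" for k in range(8)]
    truth = synthetic.LearningTruth(
        b0={i: -1.0 + 0.2 * k for k, i in enumerate(ids)},
        b1={i: 0.08 + 0.02 * k for k, i in enumerate(ids)},
    )
    chick = synthetic.simulate_trials(truth, 30, seed=21, phase="chick")
    adult = synthetic.simulate_trials(truth, 100, seed=22, phase="adult")
    return truth, chick, adult
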