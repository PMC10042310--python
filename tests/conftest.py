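"""Shared fixtures: a study-scale synthetic world and its Part-1 fit.

The fit is expensive relative to everything else, so it is computed once
per session and shared by the recovery, prediction and model-comparison
tests.  The rational-world and lesioned-world datasets share a seed, which
makes their Part-1 trials identical (the generators consume randomness in
lockstep and only the combination-task probabilities differ), so a single
fit serves all evaluation scenarios.
"""

from dataclasses import replace

import numpy as np
import pytest

from pragint.fitting import FitConfig, fit_part1
from pragint.simulate import SimConfig, simulate
from pragint.tasks import ListenerModel, Task

STUDY_SEED = 11
FIT_SEED = 7


@pytest.fixture(scope="session")
def study_world():
    """Study-design synthetic data (N=60) generated by the rational model,
    plus a twin world whose combination responses come from the
    no-common-ground lesion."""
    cfg = SimConfig(n_children=60, seed=STUDY_SEED)
    trials, roster, truth = simulate(cfg)
    trials_nocg, _, _ = simulate(replace(cfg, generating_model=ListenerModel.NO_CG))
    part1_cols = trials["task"] != Task.COMBINATION.value
    assert trials[part1_cols].equals(trials_nocg[part1_cols])
    return {"trials": trials, "trials_nocg": trials_nocg, "roster": roster, "truth": truth}


@pytest.fixture(scope="session")
def study_fit(study_world):
    """Part-1 posterior for the shared study world."""
    cfg = FitConfig(chains=3, draws=1200, warmup=1200, seed=FIT_SEED)
    return fit_part1(study_world["trials"], study_world["roster"], cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
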