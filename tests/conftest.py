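"""Shared fixtures: a default simulated study, reused across test modules."""

import numpy as np
import pytest

import maskcue as mc
from maskcue import behavior as bh


@pytest.fixture(scope="session")
def exp2_stimuli():
    return mc.make_stimulus_set("exp2", mc.CueParams(), rng_seed=11)


@pytest.fixture(scope="session")
def exp2_panel():
    return mc.default_panel(30, rng_seed=11)


@pytest.fixture(scope="session")
def exp2_trials(exp2_stimuli, exp2_panel):
    return mc.simulate_trials(exp2_stimuli, exp2_panel, rng_seed=11)


@pytest.fixture(scope="session")
def exp2_accuracy(exp2_trials):
    acc, stats = bh.condition_accuracy(exp2_trials)
    pivot = acc.pivot(index="participant_id", columns="condition",
                      values="accuracy").sort_index()
    return pivot, stats


@pytest.fixture(scope="session")
def exp2_subgroups(exp2_accuracy):
    pivot, _ = exp2_accuracy
    split = bh.quintile_split(pivot["high_realism_mask"].to_dict())
    high = split.loc[split["subgroup"] == "high", "participant_id"].tolist()
    low = split.loc[split["subgroup"] == "low", "participant_id"].tolist()
    return split, high, low


@pytest.fixture(scope="session")
def six_averages(exp2_stimuli, exp2_trials, exp2_subgroups):
    from maskcue.averaging import build_six_averages

    _, high, low = exp2_subgroups
    return build_six_averages(exp2_stimuli, exp2_trials, high, low)


@pytest.fixture(scope="session")
def tiny_stimulus():
    """One quickly rendered stimulus for geometry-level tests."""
    return mc.make_stimulus("real_face", mc.CueParams(), rng_seed=5)
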