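import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import popcode

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

# Compact session layout used throughout the unit tests: four epochs of
# 800 pre-introduction frames + 4 bouts of 400 social frames with 200-frame
# gaps, plus two 800-frame baseline blocks (13,600 frames total).
SMALL_PLAN = dict(
    pre_frames=800, n_bouts=4, bout_frames=400, gap_frames=200, baseline_frames=800
)


def small_social_session(seed=0, dynamic=True, truth=None, n_neurons=60, **spec_kw):
    spec = popcode.default_social_spec(
        seed=seed, dynamic=dynamic, n_neurons=n_neurons, **(SMALL_PLAN | spec_kw)
    )
    return popcode.generate_session(spec, truth or popcode.TruthConfig())


@pytest.fixture(scope="session")
def social_session():
    """Dynamic-context session, remap off, default planted ensembles."""
    return small_social_session(seed=42)


@pytest.fixture(scope="session")
def remap_session():
    """Dynamic-context session whose social ensemble is redrawn per context."""
    return small_social_session(seed=42, truth=popcode.TruthConfig(remap=True))


@pytest.fixture(scope="session")
def null_session():
    """No planted effects: all gains 1."""
    truth = popcode.TruthConfig(
        social_frac_pos=0, social_frac_neg=0, context_frac_pos=0, context_frac_neg=0
    )
    return small_social_session(seed=7, truth=truth)


@pytest.fixture(scope="session")
def maze_session():
    spec = popcode.default_maze_spec(seed=9, n_neurons=60, hc_frames=1500, maze_frames=2000)
    truth = popcode.TruthConfig(arm_groups={"open": (0.2, 2.0, 0.5)})
    return popcode.generate_maze_session(spec, truth)
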