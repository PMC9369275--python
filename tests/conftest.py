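import numpy as np
import pytest
from hypothesis import settings

import thromboquant as tq
from thromboquant.synthetic import field_targets, sample_ground_truth

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")

SMALL_FIELD = (256, 340)


@pytest.fixture(scope="session")
def control():
    return tq.ConditionSpec.control()


@pytest.fixture(scope="session")
def small_truth(control):
    """A mid-density field with aggregates, shared across read-only tests."""
    rng = np.random.default_rng(12345)
    targets = field_targets("collagen-I", 1000.0, control, 1.0, rng)
    return sample_ground_truth(rng, targets, field_size=SMALL_FIELD)


@pytest.fixture(scope="session")
def small_brightfield(small_truth):
    return tq.render_brightfield(small_truth, seed=99)


@pytest.fixture(scope="session")
def tiny_design(control):
    """Smallest design that still exercises pairing and both image roles."""
    treated = tq.ConditionSpec(
        name="treated", effect_multipliers={1000.0: {"seeding": 0.6}}
    )
    return tq.ExperimentDesign(
        donors=3,
        duplicate_runs_per_condition=1,
        microspots=("collagen-I",),
        shear_rates=(1000.0,),
        conditions=(control, treated),
        images_per_run_brightfield=1,
        images_per_run_fluorescence=1,
        field_size=(128, 170),
        seed=7,
    )
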