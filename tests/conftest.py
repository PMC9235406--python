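import numpy as np
import pytest

from artbayes.model import ModelParams
from artbayes.simulate import GroupSpec, simulate_cohort, simulate_subject
from artbayes.task import canonical_schedule, generate_max_casts


@pytest.fixture(scope="session")
def canonical_design():
    return generate_max_casts(canonical_schedule(), seed=123)


@pytest.fixture(scope="session")
def small_cohort(canonical_design):
    """Two 6-subject groups on the canonical design, with ground truth."""
    groups = [
        GroupSpec(6, 1.4, 0.25, 0.2, 0.2, "control"),
        GroupSpec(6, 3.6, 0.07, 0.2, 0.2, "dD"),
    ]
    return simulate_cohort(groups, canonical_design, seed=11)


@pytest.fixture(scope="session")
def single_play(canonical_design):
    return simulate_subject(ModelParams(2.0, 0.3), canonical_design, seed=5)
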