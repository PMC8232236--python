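import numpy as np
import pytest

from dmnpdc.pdc import subject_connectivity
from dmnpdc.preprocessing import preprocess
from dmnpdc.synthetic import GROUPS, make_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic cohort (4 subjects/group, 60 s at 256 Hz)."""
    return make_cohort(n_per_group=4, duration_s=60.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort_tensors(small_cohort):
    """Connectivity tensors for the small cohort (full preprocessing chain,
    fixed order 6)."""
    tensors = {}
    for s in small_cohort.subjects:
        epochs = preprocess(s.recording)
        tensors[s.id] = subject_connectivity(
            epochs, order_policy=6, subject_id=s.id
        )
    return tensors


@pytest.fixture(scope="session")
def tensors_by_group(small_cohort, small_cohort_tensors):
    return {
        g: [
            small_cohort_tensors[s.id]
            for s in small_cohort.group_subjects(g)
        ]
        for g in GROUPS
    }
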