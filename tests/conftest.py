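import numpy as np
import pytest

from migroup.containers import EEGTrialSet
from migroup.montage import get_montage
from migroup.preprocess import FilterBank
from migroup.synth import SynthSpec, default_cohort_spec, generate_subject


@pytest.fixture(scope="session")
def mi22():
    return get_montage("mi22")


@pytest.fixture(scope="session")
def mu_bank():
    """Single 8-12 Hz band filter bank for cheap single-band analyses."""
    return FilterBank(bands=((8.0, 12.0),), f_min=8, f_max=12, width=4, step=2)


@pytest.fixture
def white_trials(mi22):
    """Unit-variance white-noise trials: the structureless null input."""
    rng = np.random.default_rng(42)
    data = rng.standard_normal((24, 22, 1751))
    labels = np.array(["left"] * 12 + ["right"] * 12)
    return EEGTrialSet(data=data, labels=labels, sample_rate=250.0,
                       montage=mi22, subject_id="null")


@pytest.fixture(scope="session")
def planted_subject():
    """One subject with the canonical contralateral mu-ERD plants (no jitter)."""
    spec = default_cohort_spec(seed=7, n_subjects=1, n_trials_per_class=60,
                               subject_jitter=0.0)
    return spec, generate_subject(spec, 0)


@pytest.fixture(scope="session")
def null_subject():
    """A plant-free subject under otherwise identical conditions."""
    spec = SynthSpec(n_subjects=1, n_trials_per_class=60, subject_jitter=0.0,
                     seed=8)
    return spec, generate_subject(spec, 0)
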