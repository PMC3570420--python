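import pytest

from mciconvert.cohort import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def cohort(default_spec):
    return generate_cohort(default_spec, seed=1)
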