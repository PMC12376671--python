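import pytest
from hypothesis import settings

from defekit.biometric import assemble_features
from defekit.synthetic import generate_cohort, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-sized cohort: 11 participants (5 female), 5 events each."""
    cohort = generate_cohort(11, 5, seed=1)
    return simulate_dataset(cohort, 5, seed=1)


@pytest.fixture(scope="session")
def feature_table(default_dataset):
    """Biomarker table extracted from the default dataset's raw streams."""
    return assemble_features(default_dataset)
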