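import numpy as np
import pytest
from hypothesis import settings

from cricketsen import ExperimentConfig, IndividualRecord, generate_experiment
from cricketsen.io import cohort_to_records

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_records(times, sex="male", diet="C", mating="mated", prefix="r"):
    """Records for one treatment cell from an array of death times."""
    return [
        IndividualRecord(f"{prefix}{i}", sex, diet, mating, float(t))
        for i, t in enumerate(np.asarray(times))
    ]


@pytest.fixture(scope="session")
def default_experiment():
    """One default-design synthetic experiment (cohort + calling tables)."""
    return generate_experiment(ExperimentConfig(seed=11))


@pytest.fixture(scope="session")
def default_records(default_experiment):
    cohort, _ = default_experiment
    return cohort_to_records(cohort)
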