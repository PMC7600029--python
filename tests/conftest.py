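import numpy as np
import pytest

from crystalbone.data_model import assemble_records
from crystalbone.fractures import anchor_events, qualify_fracture_events
from crystalbone.synthetic import GeneratorConfig, generate_cohort
from crystalbone.windows import build_all_windows, select_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient pan-therapeutic cohort shared across unit tests."""
    return generate_cohort(
        GeneratorConfig(n_patients=400, vocabulary_size=300, seed=101)
    )


@pytest.fixture(scope="session")
def small_records(small_cohort):
    records, _ = assemble_records(
        small_cohort.diagnoses, small_cohort.medications, small_cohort.demographics
    )
    return records


@pytest.fixture(scope="session")
def small_fractures(small_records):
    return {pid: qualify_fracture_events(rec) for pid, rec in small_records.items()}


@pytest.fixture(scope="session")
def small_anchors(small_records, small_fractures):
    return {
        pid: anchor_events(rec, small_fractures[pid])
        for pid, rec in small_records.items()
    }


@pytest.fixture(scope="session")
def small_selection(small_records, small_anchors):
    return select_cohort(small_records, small_anchors)


@pytest.fixture(scope="session")
def small_windows(small_selection, small_fractures):
    return build_all_windows(small_selection, small_fractures)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
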