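"""Shared fixtures: one synthetic cohort per session plus its cascade run."""
import pytest

from tailvar import SimulationConfig, generate_cohort, run_cascade


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort: 2 x 100 kb chromosomes, 4 + 4
    samples, 50 + 50 breed-specific, 100 shared, 10 artifacts per class."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def cascade(cohort):
    return run_cascade(cohort.records, cohort.reference, cohort.masks, cohort.known_db)


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    from tailvar import write_cohort

    out = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(cohort, out)
    return paths
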