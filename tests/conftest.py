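import pytest

from ppticc import Design, VarianceComponents


@pytest.fixture(scope="session")
def paper_components() -> VarianceComponents:
    """The published lumbar-PPT variance components (N^2) with a 50 N mean."""
    return VarianceComponents(
        grand_mean=50.0,
        sigma2_subj=222.28,
        sigma2_sess=4.83,
        sigma2_side=9.72,
        sigma2_sss=34.63,
        sigma2_reps=45.77,
    )


@pytest.fixture(scope="session")
def study_design() -> Design:
    """The study layout: 20 subjects x 2 sessions x 2 sides x 10 repetitions."""
    return Design(n_subjects=20, n_sessions=2, n_sides=2, n_repetitions=10)


@pytest.fixture(scope="session")
def toy_design() -> Design:
    return Design(n_subjects=4, n_sessions=2, n_sides=2, n_repetitions=3)
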