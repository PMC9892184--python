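import pytest

from cavbmonkey.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small noise-free cohort with guaranteed TdP-susceptible animals:
    6-h recordings so the 1-3 h post-dose window is fully contained."""
    cfg = CohortConfig(
        n_animals=4,
        months=(-1, 1, 2, 3),
        seed=11,
        recording_duration_h=6.0,
        noise_scale=0.0,
        tdp_prone_fraction=1.0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = CohortConfig(
        n_animals=3,
        months=(-1, 1, 2),
        seed=5,
        recording_duration_h=6.0,
        tdp_prone_fraction=0.5,
    )
    return generate_cohort(cfg)
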