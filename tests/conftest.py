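import pytest

from evotraj.synth import default_archetypes, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """36 samples, 12 per archetype, with truth records."""
    return simulate_cohort(n_per_archetype=12, seed=7, noise=0.1)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes(n_events=30, seed=0)
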