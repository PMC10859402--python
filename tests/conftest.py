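import pytest
from hypothesis import HealthCheck, settings

from hla_ept.examples import worked_example_catalog
from hla_ept.simulate import (
    SimulationConfig,
    generate_catalog,
    generate_panel,
    generate_submissions,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_catalog():
    """The hand-built catalogue with the canonical ambiguity/null structures."""
    return worked_example_catalog()


@pytest.fixture(scope="session")
def default_scheme():
    """One default-condition synthetic scheme (24 labs x 12 samples x 8 loci)."""
    config = SimulationConfig(seed=11)
    catalog = generate_catalog(config)
    panel = generate_panel(catalog, config)
    records, truths = generate_submissions(panel, catalog, config)
    return config, catalog, panel, records, truths


@pytest.fixture(scope="session")
def small_scheme():
    """A compact scheme for fast statistics tests."""
    config = SimulationConfig(
        seed=3, loci=("A", "DQB1"), groups_per_locus=4, n_labs=6
    )
    catalog = generate_catalog(config)
    panel = generate_panel(catalog, config)
    records, truths = generate_submissions(panel, catalog, config)
    return config, catalog, panel, records, truths
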