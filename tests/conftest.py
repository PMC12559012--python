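import pytest

import denomweight as dw


@pytest.fixture(scope="session")
def window():
    return dw.EngagementWindow()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down registry for fast unit tests."""
    return dw.GeneratorConfig(n_reference_adults=30_000, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_config):
    reference = dw.generate_reference(small_config)
    registry, truth = dw.generate_registry(small_config, reference)
    return reference, registry, truth


@pytest.fixture(scope="session")
def weighted_small(small_config, small_tables, window):
    reference, registry, _ = small_tables
    weighted, log = dw.weight_pipeline(registry, reference, window)
    return weighted, log


@pytest.fixture(scope="session")
def default_config():
    """The generator's default study conditions (100,000 reference adults)."""
    return dw.GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def default_tables(default_config):
    reference = dw.generate_reference(default_config)
    registry, truth = dw.generate_registry(default_config, reference)
    return reference, registry, truth


@pytest.fixture(scope="session")
def weighted_default(default_config, default_tables, window):
    reference, registry, _ = default_tables
    weighted, log = dw.weight_pipeline(registry, reference, window)
    return weighted, log
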