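import pytest
from hypothesis import HealthCheck, settings

from rumenzeta import (
    GeneratorConfig,
    assemble_integrated_dataset,
    generate_blocks,
    load_t1_means,
    load_t2_means,
)
from rumenzeta.io import ExperimentDesign

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def t1_means():
    return load_t1_means()


@pytest.fixture(scope="session")
def t2_means():
    return load_t2_means()


@pytest.fixture(scope="session")
def fixture_dataset(t1_means, t2_means):
    """Integrated dataset built from the bundled condition-mean tables."""
    return assemble_integrated_dataset(t1_means, t2_means)


@pytest.fixture(scope="session")
def small_design():
    """2 SSA x 2 ST x 2 replicates: cheap but structurally complete."""
    return ExperimentDesign(
        ssa_levels=(3.37, 4.44), st_levels=(53.95, 36.07), replicates=2
    )


@pytest.fixture(scope="session")
def small_blocks(small_design):
    return generate_blocks(GeneratorConfig(design=small_design, seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_blocks):
    t1, t2, _ = small_blocks
    return assemble_integrated_dataset(t1, t2)
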