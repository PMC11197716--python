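import pytest

from pasm import synthetic_data
from pasm.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def oracle_config():
    """Two-crop instance with a hand-derived interior optimum."""
    return GeneratorConfig(
        eq_land_ha=100.0,
        eq_yields_t_per_ha=[10.0, 5.0],
        eq_costs_yuan_per_ha=[1000.0, 500.0],
        eq_demand_a=[2000.0, 3000.0],
        eq_demand_b=[1.0, 2.0],
    )


@pytest.fixture(scope="session")
def oracle_instance(oracle_config):
    return synthetic_data.generate_known_equilibrium_instance(oracle_config, seed=1)


@pytest.fixture(scope="session")
def capped_oracle_instance(oracle_config):
    from dataclasses import replace

    cfg = replace(oracle_config, eq_pesticide_kg_per_ha=[10.0, 2.0])
    return synthetic_data.generate_known_equilibrium_instance(cfg, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """Tiny but complete layout for fast grid runs."""
    return GeneratorConfig(
        n_districts=2,
        n_crops=4,
        mean_land_ha=500.0,
        n_total=40,
        n_mechanized=22,
        survey_noise_sigma=0.02,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return synthetic_data.generate_instance(small_config, seed=7)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default layout (9 districts x 15 crops)."""
    return synthetic_data.generate_instance(GeneratorConfig(), seed=42)
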