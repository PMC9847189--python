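import pytest

from schoolfoodenv.synthetic import ScenarioConfig, generate_city


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """5x5 city with a central 3x3 low-income cluster, small tracts."""
    cluster = frozenset((r, c) for r in range(1, 4) for c in range(1, 4))
    return ScenarioConfig(
        grid_rows=5, grid_cols=5, tracts_per_neighborhood=2,
        population_per_tract=300.0, low_income_cluster=cluster,
        background_low_income_prop=0.3, cluster_low_income_prop=0.9,
        schools_per_neighborhood=2, seed=42,
    )


@pytest.fixture(scope="session")
def small_city(small_scenario):
    return generate_city(small_scenario)
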