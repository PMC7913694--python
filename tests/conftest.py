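import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from orthopath import Config, SimulationConfig, generate, run_all
from orthopath.orthology import OrthologyTable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_orthology(groups: dict[str, dict[str, list[str]]]) -> OrthologyTable:
    """Build a table from {og: {organism: [genes]}} literals."""
    rows = [
        {"og_id": og, "organism": org, "gene_id": g}
        for og, orgs in groups.items()
        for org, genes in orgs.items()
        for g in genes
    ]
    return OrthologyTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A fast, fully featured synthetic study for integration tests."""
    return SimulationConfig(
        rng_seed=7,
        n_ogs=600,
        n_pathways=24,
        pathway_size_range=(12, 30),
        n_housekeeping=4,
        n_planted_per_class=2,
        n_unassigned_genes=50,
        n_annotated_ogs=100,
        n_interactions=60,
    )


@pytest.fixture(scope="session")
def small_data(small_sim_config):
    return generate(small_sim_config)


@pytest.fixture(scope="session")
def small_run(small_data):
    return run_all(Config(rng_seed=7, top_n=60), small_data)
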