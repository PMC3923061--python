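import pytest

from strainscan import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A small but complete cohort: 5 genes in 2 groups, 2+2 strains."""
    return CohortConfig(
        n_genes=5,
        group_sizes={"AA": 3, "RP": 2},
        n_strains_per_species=2,
        coupling={("AA", "growth_rate", "xylulose"): -0.79},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort at the study's default structure."""
    cfg = CohortConfig(
        n_genes=200,
        group_sizes={"AA": 30, "RP": 15, "PPP": 10},
        seed=3,
    )
    return cfg, generate_cohort(cfg)
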