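import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fxiassoc import LocusSpec, SimulationConfig, simulate_genotypes, simulate_phenotype


@pytest.fixture()
def rng():
    # fresh, identically-seeded stream per test: results do not depend on
    # which other tests ran first
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_cohort():
    """n=110, one 12-kb locus, 40 variants in moderate-LD blocks, covariate
    effects only (global null). Shared across tests that only read it."""
    mafs = tuple(np.linspace(0.02, 0.45, 40))
    config = SimulationConfig(
        n_individuals=110,
        loci=(
            LocusSpec(
                "L", "chr3", 1, 12_000, mafs=mafs, ld_blocks=((10, 0.7),) * 4
            ),
        ),
        beta_age=0.2,
        beta_sex=-5.0,
        mean=120.0,
        resid_sd=30.0,
        seed=7,
    )
    genotypes, records = simulate_genotypes(config)
    phenotypes = simulate_phenotype(genotypes, config)
    return config, genotypes, records, phenotypes
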