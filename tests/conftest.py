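import numpy as np
import pandas as pd
import pytest

from rvliab.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_effect_cohort():
    """A modest ascertained trio cohort with a real damaging-PTV effect,
    shared across tests (simulation is deterministic under the seed)."""
    cfg = SimulationConfig(
        n_families=400, seed=20240917, n_genes=60,
        effect_sizes={"damaging_PTV": 0.8, "damaging_missense": 0.0, "synonymous": 0.0},
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no variant effects (the burden null)."""
    cfg = SimulationConfig(
        n_families=400, seed=7, n_genes=60,
        effect_sizes={"damaging_PTV": 0.0, "damaging_missense": 0.0, "synonymous": 0.0},
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def gene_table():
    """A small hand-built gene metadata table covering several strata."""
    rng = np.random.default_rng(5)
    n = 40
    return pd.DataFrame({
        "gene_id": [f"G{i}" for i in range(n)],
        "loeuf_decile": ([1] * 10 + [2] * 10 + [5] * 10 + [9] * 10),
        "brain_expression": np.round(rng.lognormal(2, 1, n), 3),
        "cds_length": rng.integers(300, 9000, n),
        "sfari": [i < 5 for i in range(n)],
        "sfari_loeuf1": [i < 5 for i in range(n)],
        "fetal_male_biased": False, "fetal_female_biased": False,
        "adult_male_biased": False, "adult_female_biased": False,
        "mutation_rate_ptv": 1e-5, "mutation_rate_missense": 3e-5,
        "mutation_rate_synonymous": 1.5e-5,
    })
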