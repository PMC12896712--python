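import numpy as np
import pytest

from crosspop_gs import evaluation, workflow_io

# Miniature three-population configuration used by unit and integration
# tests: same structure as the desk profile, ~20x cheaper.
TINY_CONFIG = {
    "genome": {"n_chromosomes": 2, "total_length_cm": 150.0,
               "n_markers": 300, "n_qtl": 60},
    "trait": {"h2": 0.42, "phenotypic_variance": 1.0, "gamma_shape": 0.4,
              "fixed_effect_mean": 0.0},
    "common": {"hp_phases": [[30, 80, 80]], "mutation_rate": 2.5e-5},
    "populations": {
        "A": {"hp_phases": [[10, 60, 60], [3, 60, 120]],
              "recent": {"n_sires": 8, "n_dams": 40, "n_generations": 6,
                         "sire_replacement": 0.5, "dam_replacement": 0.25,
                         "offspring_per_dam": 1},
              "mutation_rate": 2.5e-5, "missing_phenotype_rate": 0.05},
        "B": {"hp_phases": [[10, 50, 30], [3, 30, 120]],
              "recent": {"n_sires": 8, "n_dams": 42, "n_generations": 6,
                         "sire_replacement": 0.5, "dam_replacement": 0.25,
                         "offspring_per_dam": 1},
              "mutation_rate": 2.5e-5, "missing_phenotype_rate": 0.05},
        "C": {"hp_phases": [[5, 80, 80], [6, 80, 10], [2, 10, 120]],
              "recent": {"n_sires": 8, "n_dams": 44, "n_generations": 6,
                         "sire_replacement": 0.5, "dam_replacement": 0.25,
                         "offspring_per_dam": 1},
              "mutation_rate": 2.5e-5, "missing_phenotype_rate": 0.05},
    },
    "analysis": {"fst_threshold": 0.05},
    "replicates": 1,
    "master_seed": 7,
}


@pytest.fixture(scope="session")
def tiny_config():
    return workflow_io.RunConfig(**{k: v for k, v in TINY_CONFIG.items()})


@pytest.fixture(scope="session")
def tiny_trio(tiny_config):
    """Three miniature populations sharing a base cohort and trait."""
    return evaluation.simulate_replicate(tiny_config, 7, 0)


@pytest.fixture(scope="session")
def desk_config():
    return workflow_io.load_profile("desk")


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
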