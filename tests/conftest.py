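import numpy as np
import pandas as pd
import pytest

from snpmap import (
    SimulationConfig,
    allelotype,
    build_pools,
    simulate_cohort,
    simulate_intensities,
)
from snpmap.cohort import Cohort, Pool, PoolDesign


@pytest.fixture(scope="session")
def fast_config() -> SimulationConfig:
    """Small all-blood cohort: quick but structurally complete (two pools per
    phenotypic cell so biological replicate groups exist, technical
    replicates, default noise)."""
    return SimulationConfig(
        n_cases=192, n_controls=192, n_snps=200, seed=7,
        target_pool_size=16, control_blood_fraction=1.0,
    )


@pytest.fixture(scope="session")
def fast_cohort(fast_config):
    return simulate_cohort(fast_config)


@pytest.fixture(scope="session")
def fast_design(fast_cohort, fast_config):
    return build_pools(fast_cohort, fast_config)


@pytest.fixture(scope="session")
def fast_matrix(fast_design, fast_cohort, fast_config):
    return simulate_intensities(fast_design, fast_cohort, fast_config)


@pytest.fixture(scope="session")
def fast_ras(fast_matrix):
    return allelotype(fast_matrix)


def make_fixed_freq_setup(doses, n_snps: int = 50):
    """Hand-built cohort and two-pool design where every pool's true allele-A
    frequency at every SNP is exactly mean(doses)/2 (equal weights).

    ``doses`` is the genotype-dose pattern of one pool's members, used for
    both the case pool and the control pool.
    """
    doses = np.asarray(doses, dtype=np.int8)
    k = len(doses)
    geno = np.tile(doses[:, None], (2, n_snps))
    individuals = pd.DataFrame(
        {
            "id": [f"i{j}" for j in range(2 * k)],
            "phenotype": ["case"] * k + ["control"] * k,
            "sex": "female",
            "stratum": "low",
            "dna_source": "blood",
        }
    )
    snp_table = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(n_snps)],
            "true_maf_control": doses.mean() / 2,
            "true_freq_case": doses.mean() / 2,
            "is_effect": False,
        }
    )
    cohort = Cohort(individuals, geno, snp_table)
    w = np.full(k, 1.0 / k)
    design = PoolDesign(
        [
            Pool("p_case", np.arange(k), individuals["id"][:k].tolist(),
                 "case", "female", "low", "blood", w),
            Pool("p_ctrl", np.arange(k, 2 * k), individuals["id"][k:].tolist(),
                 "control", "female", "low", "blood", w),
        ]
    )
    return cohort, design


@pytest.fixture
def fixed_freq_setup():
    return make_fixed_freq_setup
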