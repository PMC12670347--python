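import numpy as np
import pandas as pd
import pytest

from septrial import DGPConfig, build_cohort, compute_truth, generate_cohort
from septrial.stacking import FAST_LIBRARY


@pytest.fixture(scope="session")
def default_config() -> DGPConfig:
    return DGPConfig(n_stays=10_000, seed=42)


@pytest.fixture(scope="session")
def records(default_config) -> pd.DataFrame:
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def cohort(records, default_config) -> pd.DataFrame:
    built, _ = build_cohort(records, calibration=default_config.pmp_calibration)
    return built


@pytest.fixture(scope="session")
def truth(default_config):
    return compute_truth(default_config, n_mc=200_000, seed=5)


@pytest.fixture(scope="session")
def fast_library():
    return FAST_LIBRARY


def simulate_and_build(config: DGPConfig, seed: int):
    """One fresh cohort replicate for simulation studies."""
    rec = generate_cohort(config.replace(seed=seed))
    built, _ = build_cohort(rec, calibration=config.pmp_calibration,
                            treatments=config.treatments)
    return built


@pytest.fixture(scope="session")
def binary_confounder_config() -> DGPConfig:
    """Single binary confounder with a saturated logistic outcome model;
    the g-formula risk difference has a closed form."""
    from septrial.synthetic_cohort import CovariateSpec

    return DGPConfig(
        n_stays=5_000,
        seed=7,
        cancer_prevalences={},
        covariate_spec=[CovariateSpec("z", "bernoulli", (0.4,), "static", 0.0, 1.0)],
        treatments=("imv",),
        propensity_coefficients={"imv": {"intercept": 0.2, "z": 0.5}},
        treatment_start_distribution={
            "imv": {"p_within": 1.0, "within_beta": (1.2, 2.5), "late_scale": 30.0}},
        outcome_coefficients={"intercept": -1.0, "z": 0.8, "treat:imv": 0.7},
    )
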