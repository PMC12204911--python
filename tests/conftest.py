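import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import biometwin as bt

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ae_cohort():
    """Continuous AE cohort (a2=0.6) with covariate mean effects."""
    cfg = bt.SimulationConfig(
        n_mz_pairs=400, n_dz_pairs=400,
        continuous_traits=[bt.ContinuousTraitSpec(
            "y", bt.VarianceComponents(a2=0.6, e2=0.4, total_sd=0.5),
            bt.MeanModel(intercept=-3.0, beta_sex=0.3, beta_age=-0.02,
                         beta_height=0.04))],
        seed=11)
    cohort, truth = bt.simulate_cohort(cfg, seed=11)
    return cohort, truth


@pytest.fixture(scope="session")
def ae_pairs(ae_cohort):
    cohort, _ = ae_cohort
    pairs, _ = bt.assemble_pairs(cohort, "y")
    return pairs


@pytest.fixture(scope="session")
def binary_pairs():
    """Liability AE pairs (a2=0.5) at a common-trait prevalence of 10%."""
    cfg = bt.SimulationConfig(
        n_mz_pairs=800, n_dz_pairs=800,
        binary_traits=[bt.BinaryTraitSpec(
            "d", bt.VarianceComponents(a2=0.5, e2=0.5), prevalence=0.10,
            threshold=bt.ThresholdModel(0.0, 0.2, 0.01, 0.0))],
        seed=7)
    cohort, _ = bt.simulate_cohort(cfg, seed=7)
    pairs, _ = bt.assemble_pairs(cohort, "d")
    pairs.y = pairs.y.astype(float)
    return pairs


@pytest.fixture(scope="session")
def continuous_model_fits(ae_pairs):
    """SAT + structured fits of the AE cohort, shared across tests."""
    return {lbl: bt.fit_continuous(ae_pairs, model_label=lbl, seed=3,
                                   ci_method=None)
            for lbl in ("SAT", "ACE", "ADE", "AE", "CE", "E")}
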