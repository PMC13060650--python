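import numpy as np
import pandas as pd
import pytest

import mesomark as mm


@pytest.fixture(scope="session")
def small_cohort():
    """Beta cohort with 50 injected hypermethylated sites among 1000 CpGs."""
    cfg = mm.SyntheticCohortConfig(
        n_per_group=30, n_cpg=1000, n_informative=50, tumor_delta=0.4, seed=11
    )
    beta, truth = mm.generate_beta_matrix(cfg, ["tumor", "pleura", "blood"], "tumor")
    return cfg, beta, truth


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    _, beta, _ = small_cohort
    return mm.generate_target_panel(len(beta.cpg_ids), seed=11, cpg_ids=beta.cpg_ids)


@pytest.fixture(scope="session")
def two_step_cohort():
    return mm.generate_two_step_cohort(seed=5)


@pytest.fixture(scope="session")
def processed(two_step_cohort):
    normalized, qc, exclusions, retained = mm.qc_normalize(two_step_cohort.matrix)
    return normalized, qc, exclusions, retained


def exact_moments_vector(rng, n, mean, sd):
    """Sample vector with exactly the requested mean and sample SD."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
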