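import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from idscn.io import CovariateTable, RegionalVolumeTable
from idscn.synthetic import CohortSpec, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small healthy-only cohort: 12 reference subjects, 4 patients,
    6 regions, no injected aberrations."""
    return CohortSpec(n_reference=12, n_patients=4, n_regions=6,
                      aberrant_edges=None, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


def random_tables(rng: np.random.Generator, n: int, n_regions: int):
    """Random well-conditioned volume + covariate tables for oracle checks."""
    ids = [f"S{k:03d}" for k in range(n)]
    sex = np.tile([0.0, 1.0], n // 2 + 1)[:n]  # balanced: design stays full rank
    rng.shuffle(sex)
    cov = np.column_stack([
        rng.uniform(50, 80, n),
        sex,
        rng.uniform(6, 20, n),
        rng.normal(1435, 130, n),
    ])
    V = rng.uniform(4, 14, n_regions) + rng.normal(0, 1.0, (n, n_regions))
    V += 0.002 * (cov[:, 3:4] - 1435)  # mild TIV dependence
    volumes = RegionalVolumeTable(pd.DataFrame(
        V, index=ids, columns=[f"R{r:02d}" for r in range(n_regions)]
    ))
    covariates = CovariateTable(pd.DataFrame(
        cov, index=ids, columns=["age", "sex", "education", "tiv"]
    ))
    return volumes, covariates
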