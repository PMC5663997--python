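import numpy as np
import pandas as pd
import pytest

from reomet.reo_classifier import GenePairSignature
from reomet.synth import CohortParams, generate_cohort


@pytest.fixture
def small_expr():
    """4 genes x 3 samples with unambiguous orderings."""
    return pd.DataFrame(
        {
            "s1": [5.1, 4.9, 7.0, 2.0],
            "s2": [4.0, 4.5, 1.0, 3.0],
            "s3": [6.0, 6.0, 2.0, 2.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )


@pytest.fixture
def two_pair_signature():
    return GenePairSignature((("gA", "gB"), ("gC", "gD")))


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort shared across tests."""
    return generate_cohort(CohortParams(seed=11))


@pytest.fixture(scope="session")
def occult_cohort():
    """Occult-contamination scenario cohort (phi = 0.2)."""
    return generate_cohort(CohortParams.occult_scenario(seed=7, phi_occult=0.2))


def random_expression(rng: np.random.Generator, n_genes: int = 30, n_samples: int = 12):
    values = rng.normal(7.0, 1.5, size=(n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
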