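import numpy as np
import pandas as pd
import pytest

from hgclust.synthetic import SyntheticParams, generate_cohort
from hgclust.varclust import LikertMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-scale cohort: 391 participants, 37+22 symptoms."""
    return generate_cohort(SyntheticParams(seed=5))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for plumbing tests."""
    return generate_cohort(SyntheticParams(n_participants=150, seed=11))


@pytest.fixture(scope="session")
def clean_two_cluster():
    """Two tight planted clusters, no noise columns, no missingness."""
    params = SyntheticParams(n_participants=400, cluster_sizes=(5, 5),
                             n_noise_symptoms=0, beta_hg=(0.3, 0.3),
                             loading_range=(0.8, 0.9), missing_rate=0.0, seed=3)
    return generate_cohort(params)


def likert_of(cohort) -> LikertMatrix:
    return LikertMatrix(
        cohort.survey.set_index("participant_id")[cohort.symptom_columns])


@pytest.fixture(scope="session")
def two_cluster_likert(clean_two_cluster):
    return likert_of(clean_two_cluster)


def exact_corr_columns(n: int, rho: float, p: int = 2, seed: int = 0) -> pd.DataFrame:
    """Columns with *sample* correlation exactly rho (equicorrelated), unit variance.

    Built from an orthonormalised random basis, so closed-form reliability and
    homogeneity identities hold exactly, not just in expectation.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, p + 1))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    g = q[:, 0]
    cols = {}
    for j in range(p):
        e = q[:, j + 1]
        x = np.sqrt(rho) * g + np.sqrt(1 - rho) * e
        cols[f"v{j}"] = x / x.std(ddof=1)
    return pd.DataFrame(cols)
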