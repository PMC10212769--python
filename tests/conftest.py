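import numpy as np
import pandas as pd
import pytest

from immunoedit.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A small but complete cohort configuration used across tests."""
    return CohortConfig(
        n_patients=4,
        regions_per_patient=3,
        n_proteins=60,
        protein_length_range=(80, 200),
        mutations_per_region=25,
        peptides_per_sample=120,
        taa_log2_boost_excluded=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def random_proteome(rng, n_proteins=50, length_range=(40, 120)):
    """Plain random proteome for oracle tests."""
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return {
        f"PROT{i:03d}": "".join(rng.choice(aa, size=rng.integers(*length_range)))
        for i in range(n_proteins)
    }
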