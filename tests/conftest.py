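import numpy as np
import pandas as pd
import pytest

from selectiscreen import synthetic_data as sd
from selectiscreen.chem_data import DescriptorMatrix


@pytest.fixture(scope="session")
def small_labeled_matrix() -> DescriptorMatrix:
    """60-compound matrix with 10 latent factors, 2 copies each, clear signal."""
    cfg = sd.GeneratorConfig(
        seed=11,
        n_compounds=60,
        n_active=30,
        n_latent_factors=10,
        copies_per_factor=2,
        noise_sd=0.2,
        family_counts={"other": 25},
    )
    matrix, _ = sd.gen_descriptor_matrix(cfg)
    return matrix


@pytest.fixture(scope="session")
def planted_factor_matrix():
    """300 x 60 matrix from 30 latent factors (2 noisy copies each) + truth."""
    cfg = sd.GeneratorConfig(
        seed=7,
        n_compounds=300,
        n_active=151,
        n_latent_factors=30,
        copies_per_factor=2,
        noise_sd=0.3,
        family_counts={"other": 60},
    )
    return sd.gen_descriptor_matrix(cfg)


def make_matrix(values: np.ndarray, labels=None, names=None) -> DescriptorMatrix:
    """Build a DescriptorMatrix from a raw array, for hand-constructed cases."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"x{j}" for j in range(p)]
    ids = [f"c{i}" for i in range(n)]
    return DescriptorMatrix(
        values=pd.DataFrame(values, index=ids, columns=names),
        labels=None if labels is None else pd.Series(labels, index=ids),
    )
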