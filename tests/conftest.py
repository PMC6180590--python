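import numpy as np
import pandas as pd
import pytest

from thresher.containers import ExpressionMatrix
from thresher.synthetic_data import generate_default_bundle, generate_factor_dataset


@pytest.fixture(scope="session")
def bundle():
    """The standard study bundle: 5 factors (one sign-split), 10 noise genes."""
    return generate_default_bundle(seed=11)


@pytest.fixture(scope="session")
def signal_only():
    """Clean 5-factor data: 40 signal genes, no noise genes, low noise."""
    return generate_factor_dataset(
        n_samples=500, n_factors=5, genes_per_factor=8, noise_sd=0.3, seed=42
    )


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.standard_normal((3, 4)).round(4),
        index=["GENEA", "GENEB", "GENEC"],
        columns=[f"S{i}" for i in range(4)],
    )
    return ExpressionMatrix(values)
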