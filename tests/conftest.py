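import numpy as np
import pandas as pd
import pytest

from tp53sig import (
    ExpressionMatrix,
    SyntheticConfig,
    default_signature,
    generate_cohort,
    load_signature,
)


@pytest.fixture(scope="session")
def sig():
    """Standard-size placeholder panel: 22 up, 9 down, 5 control genes."""
    return default_signature()


@pytest.fixture(scope="session")
def tiny_sig():
    """Reduced synthetic panel (3 up, 2 down) for hand-computable scores."""
    return load_signature(
        {"up": ["U1", "U2", "U3"], "down": ["D1", "D2"]},
        allow_nonstandard_sizes=True,
    )


@pytest.fixture(scope="session")
def cohort(sig):
    """One deterministic default-condition cohort shared across tests."""
    return generate_cohort(SyntheticConfig(seed=11), sig)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_matrix(counts: np.ndarray, genes, samples=None, platform="ncounter") -> ExpressionMatrix:
    counts = np.asarray(counts, dtype=float)
    if samples is None:
        samples = [f"S{i}" for i in range(counts.shape[0])]
    return ExpressionMatrix(pd.DataFrame(counts, index=samples, columns=list(genes)), platform=platform)
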