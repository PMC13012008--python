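from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from napy import (
    ExpressionMatrix,
    SimulationConfig,
    make_worked_example,
    simulate,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def small_cohort():
    """Compact default-condition cohort for module-level tests."""
    return simulate(SimulationConfig(n_samples=160, n_noise_genes=120, seed=11))


@pytest.fixture
def toy_matrix():
    """6-gene, 8-sample deterministic matrix for correlation tests."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(0, 8, size=(6, 8)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(8)],
    )
    return ExpressionMatrix(values, "log2_tpm1")


def golden(name: str, **kw) -> pd.DataFrame:
    return pd.read_csv(DATA / name, sep="\t", **kw)
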