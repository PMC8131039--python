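import numpy as np
import pandas as pd
import pytest

from gapsel.io_tables import GenotypeTable


@pytest.fixture
def toy_genotypes() -> GenotypeTable:
    """4 hybrids x 2 markers, complete calls."""
    calls = pd.DataFrame(
        {
            "m1": ["A:A", "A:A", "A:G", "A:G"],
            "m2": ["C:C", "C:T", "C:T", "C:C"],
        },
        index=pd.Index(["h1", "h2", "h3", "h4"], name="hybrid_id"),
        dtype=object,
    )
    return GenotypeTable(calls)


@pytest.fixture
def toy_phenotypes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hybrid_id": ["h1", "h2", "h3", "h4"],
            "trait": ["firmness"] * 4,
            "opv": [1.0, 3.0, 5.0, 7.0],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
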