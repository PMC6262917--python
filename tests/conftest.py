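import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lepdiv.io import AbundanceTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_abundance(counts, habitats=None, pairs=None):
    """Small AbundanceTable from a 2-D count array."""
    counts = np.asarray(counts, dtype=int)
    n = counts.shape[0]
    habitats = habitats or ["broadleaf", "plantation"] * (n // 2 + 1)
    pairs = pairs or [f"pair{i // 2 + 1:02d}" for i in range(n)]
    index = [f"site{i + 1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "pair_id": pairs[:n],
            "habitat": habitats[:n],
            "year": [2014 if i < n // 2 else 2015 for i in range(n)],
            "month": [("june", "july", "august")[i % 3] for i in range(n)],
        },
        index=index,
    )
    species = [f"sp{j + 1:03d}" for j in range(counts.shape[1])]
    return AbundanceTable(
        meta=meta, counts=pd.DataFrame(counts, index=index, columns=species)
    )


@pytest.fixture
def two_site_table():
    return make_abundance([[10, 3, 0, 7], [0, 5, 5, 0]])


@pytest.fixture
def block_z():
    """10 species in 2 functional blocks of 5: within-block similarity 1."""
    from lepdiv.similarity import SimilarityMatrix

    Z = np.zeros((10, 10))
    Z[:5, :5] = 1.0
    Z[5:, 5:] = 1.0
    return SimilarityMatrix([f"sp{j + 1:03d}" for j in range(10)], Z)


def random_community(rng, max_s=20):
    """Random relative abundance vector and unit-diagonal similarity matrix."""
    s = int(rng.integers(2, max_s))
    p = rng.dirichlet(np.ones(s))
    A = rng.random((s, s))
    Z = (A + A.T) / 2
    np.fill_diagonal(Z, 1.0)
    return p, Z
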