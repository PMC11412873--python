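import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cryocomp.io_formats import GeneCountMatrix
from cryocomp.orthogroup_shift import NormalizedMatrix


@pytest.fixture
def small_matrix() -> GeneCountMatrix:
    """4 orthogroups x 4 species, two groups of two."""
    counts = pd.DataFrame(
        {
            "p1": [2, 3, 5, 0],
            "p2": [4, 3, 6, 1],
            "b1": [6, 3, 1, 4],
            "b2": [8, 3, 0, 5],
        },
        index=["OG1", "OG2", "OG3", "OG4"],
    )
    groups = {"p1": "psychrophile", "p2": "psychrophile", "b1": "other", "b2": "other"}
    return GeneCountMatrix(counts, groups)


def normalized_from(scores: dict[str, list[float]], index: list[str]) -> NormalizedMatrix:
    """Build a NormalizedMatrix directly from per-species score columns."""
    return NormalizedMatrix(scores=pd.DataFrame(scores, index=index, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
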