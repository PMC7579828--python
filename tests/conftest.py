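import numpy as np
import pandas as pd
import pytest

from shedeval.io_formats import build_pedigree
from shedeval.simulate import SimConfig, simulate_pedigree


@pytest.fixture(scope="session")
def trio_pedigree():
    """Sire, dam, one non-inbred offspring."""
    return build_pedigree(
        pd.DataFrame(
            {"animal": ["s", "d", "x"], "sire": ["", "", "s"], "dam": ["", "", "d"]}
        )
    )


@pytest.fixture(scope="session")
def small_pedigree():
    """~80-animal random-mating pedigree, two generations."""
    cfg = SimConfig(n_founders=16, n_generations=2, progeny_per_dam=2, seed=5)
    return simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def fullsib_inbred_pedigree():
    """Parents -> two full sibs -> their inbred offspring (F = 0.25)."""
    return build_pedigree(
        pd.DataFrame(
            {
                "animal": ["a", "b", "c", "d", "e"],
                "sire": ["", "", "a", "a", "c"],
                "dam": ["", "", "b", "b", "d"],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
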