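import numpy as np
import pandas as pd
import pytest

from brainaging import synthdata as sd
from brainaging.normalize import log_cpm


@pytest.fixture(scope="session")
def regions8():
    return {f"R{i}": ("cortex" if i < 5 else "noncortex") for i in range(8)}


@pytest.fixture(scope="session")
def design8(regions8):
    """4 young + 3 aged individuals x 8 regions x 2 hemispheres (112 samples)."""
    return sd.make_design(n_young=4, n_aged=3, regions=regions8, seed=0)


@pytest.fixture(scope="session")
def group_cols(design8):
    meta = design8.samples
    return (
        meta.index[meta["age_group"] == "young"],
        meta.index[meta["age_group"] == "aged"],
    )


@pytest.fixture(scope="session")
def null_counts(design8):
    """Counts with no planted effects at all."""
    counts, truth = sd.simulate_counts(design8, sd.TruthParams(n_genes=500), seed=11)
    return counts, truth


@pytest.fixture(scope="session")
def module_dataset(design8):
    """Three planted modules (one gaining connectivity in aged) + background."""
    mods = (
        sd.ModuleSpec(size=60, r_young=0.35, r_aged=0.7),
        sd.ModuleSpec(size=50, r_young=0.7, r_aged=0.7),
        sd.ModuleSpec(size=40, r_young=0.7, r_aged=0.7),
    )
    params = sd.TruthParams(n_genes=1000, modules=mods)
    counts, truth = sd.simulate_counts(design8, params, seed=5)
    return log_cpm(counts), truth
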