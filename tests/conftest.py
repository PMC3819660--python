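import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from orgflow import CountMatrix, clean_counts, estimate_abundance
from orgflow.synthetic import SimulationSpec, simulate


@pytest.fixture()
def toy_counts() -> CountMatrix:
    """Three scaffolds, two samples, hand-checkable numbers."""
    counts = pd.DataFrame(
        {"S1": [10, 20, 40], "S2": [5, 0, 100]},
        index=pd.Index(["g1", "g2", "g3"], name="scaffold"),
    )
    lengths = pd.Series([100, 200, 400], index=counts.index, name="length")
    return CountMatrix(counts=counts, lengths=lengths)


@pytest.fixture(scope="session")
def sim_default():
    """The reference synthetic study: 2000 genes, 3 organs, 5% DE at 8-fold."""
    return simulate(SimulationSpec(seed=20260920))


@pytest.fixture(scope="session")
def sim_abundance(sim_default):
    cm = CountMatrix(counts=sim_default.counts, lengths=sim_default.lengths)
    return estimate_abundance(clean_counts(cm))
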