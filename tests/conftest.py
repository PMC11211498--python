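import numpy as np
import pytest

from isletsplice import CassetteExonEvent, JunctionCounts, SimConfig, simulate_dataset


@pytest.fixture
def plus_event():
    return CassetteExonEvent(
        event_id="E1", gene="GENE1", chrom="chr1", strand="+",
        up_exon=(100, 200), cassette=(300, 350), down_exon=(500, 600))


@pytest.fixture
def small_counts():
    return JunctionCounts(
        cells=["c1", "c2"], events=["E1", "E2"],
        I=np.array([[30, 0], [0, 40]]), S=np.array([[10, 0], [40, 0]]))


@pytest.fixture(scope="session")
def default_dataset():
    """One default-parameter synthetic dataset shared across tests."""
    return simulate_dataset(SimConfig(seed=1))
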