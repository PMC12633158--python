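import numpy as np
import pytest

from qsimcells import GeneSpec, Topology
from qsimcells.presets import case1_config, case2_config


@pytest.fixture
def demo_genes():
    """The 10-gene two-cell-type demo register (5 CT1 + 5 CT2 genes)."""
    return case1_config().gene_specs()


@pytest.fixture
def cascade():
    return Topology(((3, 5), (5, 7), (7, 0)), scope="inter")


@pytest.fixture
def control_link():
    return Topology(((2, 1),), scope="intra")


@pytest.fixture
def small_case1():
    return case1_config(seed=1, shots=150)


@pytest.fixture
def small_case2():
    return case2_config(seed=1, shots=150)


def single_gene(activation, name="g", cell_type="CT1", index=0):
    return GeneSpec(
        name=name, activation=activation, cell_type=cell_type,
        global_index=index, local_index=index,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
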