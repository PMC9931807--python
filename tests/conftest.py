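import pytest

from bca.simulators import (
    benchmark_collider_dag,
    sample_binary_dag,
    sample_ising_mh,
    six_node_model,
)


@pytest.fixture(scope="session")
def six_node():
    """The 6-node Ising benchmark: (params, ground-truth graph)."""
    return six_node_model()


@pytest.fixture(scope="session")
def ising6_data(six_node):
    """One 5000-sample Metropolis-Hastings draw from the 6-node model."""
    params, _ = six_node
    return sample_ising_mh(params, 5000, seed=1)


@pytest.fixture(scope="session")
def collider():
    """The 5-node collider DAG benchmark: (DirectedGraph, CPTs)."""
    return benchmark_collider_dag()


@pytest.fixture(scope="session")
def collider_data(collider):
    dag, cpts = collider
    return sample_binary_dag(dag, cpts, 5000, seed=7)
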