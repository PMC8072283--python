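import numpy as np
import pytest

from hetdti import (
    EdgeTypeSpec,
    HeteroNetwork,
    NodeSpace,
    SynthConfig,
    generate_network,
)

TINY_COUNTS = {"drug": 20, "protein": 25, "disease": 12, "side_effect": 10}
TINY_DENSITIES = {
    "drug_target": 0.06,
    "drug_drug": 0.08,
    "protein_protein": 0.06,
    "drug_disease": 0.06,
    "drug_sideeffect": 0.06,
    "protein_disease": 0.06,
}


def tiny_config(seed=0, **kw):
    base = dict(counts=dict(TINY_COUNTS), d_true=4,
                densities=dict(TINY_DENSITIES), flip_prob=0.0, seed=seed)
    base.update(kw)
    return SynthConfig(**base)


@pytest.fixture
def tiny_net():
    net, _ = generate_network(tiny_config())
    return net


@pytest.fixture
def tiny_net_truth():
    return generate_network(tiny_config())


def path_network():
    """3-node path a-b-c on a single binary drug-drug edge type, with the
    minimum one node of every other type (all isolated)."""
    space = NodeSpace(counts={"drug": 3, "protein": 1, "disease": 1, "side_effect": 1})
    spec = EdgeTypeSpec("drug_drug", "drug", "drug", symmetric=True)
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return HeteroNetwork(space=space, edge_types={spec.name: spec},
                         matrices={spec.name: adj})


@pytest.fixture
def path_net():
    return path_network()
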