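import numpy as np
import pytest

from agnostos import simulate as sim
from agnostos.model import GeneCluster


@pytest.fixture(scope="session")
def small_truth_bundle():
    """A compact simulated dataset shared by read-only tests."""
    genes, membership, truth = sim.simulate_families(
        n_families=40, genes_per_family=10, mutation_rate=0.05,
        intruder_rate=0.0, seed=11,
    )
    evidence = sim.simulate_evidence(truth, noise=0.0, seed=12)
    return genes, membership, truth, evidence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def clusters_from_membership(membership):
    return [
        GeneCluster(id=rep, representative=rep, members=set(members))
        for rep, members in membership.items()
    ]
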