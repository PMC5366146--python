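import numpy as np
import pytest

from cofunmir import (
    FixtureSpec,
    SimilarityMatrix,
    TripartiteNetwork,
    generate_fixture,
)
from cofunmir.pipeline import disease_similarity, mirna_similarity


@pytest.fixture(scope="session")
def default_fixture():
    """The default planted-module synthetic fixture (seeded)."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_similarities(default_fixture):
    fx = default_fixture
    dis = disease_similarity(fx.network, fx.ontology)
    mir = mirna_similarity(fx.network, fx.sequences)
    return dis, mir


@pytest.fixture()
def toy_similarities():
    """Hand-written 2x2 disease and miRNA similarity matrices."""
    dis = SimilarityMatrix(["d1", "d2"], np.array([[1.0, 0.6], [0.6, 1.0]]))
    mir = SimilarityMatrix(["m1", "m2"], np.array([[1.0, 0.4], [0.4, 1.0]]))
    return dis, mir


@pytest.fixture()
def fig1_network():
    """The worked 4-disease / 5-gene / 4-miRNA toy network.

    R2 and R3 are each associated with all four diseases and both target
    g4 and g5; every disease is linked to g4 and g5.  R1 and R4 are each
    associated with a single disease and target other genes.
    """
    net = TripartiteNetwork()
    diseases = ["d1", "d2", "d3", "d4"]
    for d in diseases:
        for g in ("g4", "g5"):
            net.add_disease_gene(d, g)
        net.add_disease_mirna(d, "R2")
        net.add_disease_mirna(d, "R3")
    for g in ("g4", "g5"):
        net.add_mirna_target("R2", g)
        net.add_mirna_target("R3", g)
    net.add_mirna_target("R1", "g1")
    net.add_disease_gene("d1", "g1")
    net.add_disease_mirna("d1", "R1")
    net.add_mirna_target("R4", "g2")
    net.add_mirna_target("R4", "g3")
    net.add_disease_gene("d4", "g2")
    net.add_disease_gene("d4", "g3")
    net.add_disease_mirna("d4", "R4")
    return net


def random_toy_network(rng: np.random.Generator, n_d=8, n_g=12, n_r=6) -> TripartiteNetwork:
    """A random small tripartite network for oracle-equivalence checks."""
    net = TripartiteNetwork()
    diseases = [f"d{i}" for i in range(n_d)]
    genes = [f"g{i}" for i in range(n_g)]
    mirnas = [f"r{i}" for i in range(n_r)]
    for d in diseases:
        for g in rng.choice(genes, size=rng.integers(1, 5), replace=False):
            net.add_disease_gene(d, g)
    for r in mirnas:
        for g in rng.choice(genes, size=rng.integers(1, 6), replace=False):
            net.add_mirna_target(r, g)
        for d in rng.choice(diseases, size=rng.integers(0, 5), replace=False):
            net.add_disease_mirna(d, r)
    return net
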