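import numpy as np
import pytest

import mlsolva as mv


@pytest.fixture(scope="session")
def path3_graph():
    """3-atom path graph used by hand-computed GCN examples."""
    return mv.MolGraph(tokens=[0, 1, 2],
                       adjacency=[[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture(scope="session")
def smiles_records():
    """Tiny real-SMILES dataset covering the molecules the symmetry tests use."""
    pairs = [("O", "c1ccccc1", -0.8), ("O", "CCCCCC", 2.5),
             ("O", "CCO", -5.0), ("O", "CC(C)=O", -3.8),
             ("CCO", "c1ccccc1", -4.5), ("CCO", "CCCCCC", -3.9),
             ("O", "CCCl", -0.5), ("CCO", "CCO", -5.3),
             ("O", "CCN", -4.5), ("CCO", "CC(C)=O", -4.0)]
    return [mv.SolvationRecord(solvent=mv.parse_smiles(a),
                               solute=mv.parse_smiles(b), dg_sol=g)
            for a, b, g in pairs]


@pytest.fixture(scope="session")
def gcn_results(smiles_records):
    """A small fitted GCN model over real molecules (any checkpoint works
    for the symmetry properties; a short fit keeps it realistic)."""
    model = mv.SolvationModel(smiles_records, encoder="gcn", width=12,
                              depth=2, embed_dim=8, epochs=15, batch_size=4,
                              seed=0)
    return model.fit()


@pytest.fixture(scope="session")
def synthetic_data():
    """Token-mode synthetic dataset at generator defaults (noiseless)."""
    spec = mv.SyntheticSpec(seed=0)
    return mv.generate_dataset(260, spec)


def random_graph(rng, size: int, n_tokens: int = 5) -> mv.MolGraph:
    """Random connected (tree + extra edges) graph with random tokens."""
    adjacency = np.zeros((size, size))
    for i in range(1, size):
        j = int(rng.integers(0, i))
        adjacency[i, j] = adjacency[j, i] = 1.0
    # sprinkle a few extra edges
    for _ in range(rng.integers(0, size)):
        i, j = rng.integers(0, size, size=2)
        if i != j:
            adjacency[i, j] = adjacency[j, i] = 1.0
    tokens = rng.integers(0, n_tokens, size=size)
    return mv.MolGraph(tokens=tokens, adjacency=adjacency)
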