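"""GCN and BiLM encoder semantics: worked values, symmetry, equivariance."""

import numpy as np
import pytest

import mlsolva as mv
from mlsolva.embedding import EmbeddedMolecule, embed, init_random_table
from mlsolva.encoders import (BiLMParams, bilm_encode, gcn_encode, gcn_layer,
                              init_bilm_params, init_gcn_params)

from conftest import random_graph


def _embedded(graph, dim=6, seed=0):
    vocab = set(graph.tokens.tolist())
    if graph.aux_tokens is not None:
        vocab |= set(graph.aux_tokens.tolist())
    return embed(graph, init_random_table(vocab, dim=dim, seed=seed))


class TestGCNLayer:
    def test_path_graph_worked_value(self, path3_graph):
        """Hand computation on a 3-atom path: D = diag(1,2,1), and the
        middle row of Ā H is 1/sqrt(2), so output[1] = tanh(1/sqrt 2)."""
        out = gcn_layer(np.array([[1.0], [0.0], [0.0]]), path3_graph,
                        [[1.0]], [[0.0]], [0.0])
        np.testing.assert_allclose(
            out, [[0.0], [np.tanh(1 / np.sqrt(2))], [0.0]], atol=1e-12)
        assert abs(out[1, 0] - 0.6089) < 1e-4

    def test_skip_path_only_is_elementwise_tanh(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 5)
        h = rng.normal(size=(5, 3))
        out = gcn_layer(h, g, np.zeros((3, 3)), np.eye(3), np.zeros(3))
        np.testing.assert_allclose(out, np.tanh(h), atol=1e-12)

    def test_single_atom_ignores_w1(self):
        g = mv.MolGraph(tokens=[0], adjacency=[[0.0]])
        h = np.array([[0.3, -0.7]])
        w2, b = np.eye(2) * 0.5, np.array([0.1, 0.1])
        out1 = gcn_layer(h, g, np.ones((2, 2)), w2, b)
        out2 = gcn_layer(h, g, np.full((2, 2), -9.0), w2, b)
        np.testing.assert_allclose(out1, out2, atol=1e-15)
        np.testing.assert_allclose(out1, np.tanh(h @ w2 + b), atol=1e-15)

    def test_matches_dense_arithmetic_oracle_on_random_graphs(self):
        """Independent oracle: explicit D^{-1/2} A D^{-1/2} with per-entry
        loops, no shared code with the layer implementation."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = random_graph(rng, 5)
            h = rng.normal(size=(5, 4))
            w1 = rng.normal(size=(4, 3))
            w2 = rng.normal(size=(4, 3))
            b = rng.normal(size=3)
            deg = g.adjacency.sum(axis=1)
            abar = np.zeros((5, 5))
            for i in range(5):
                for j in range(5):
                    if g.adjacency[i, j] and deg[i] > 0 and deg[j] > 0:
                        abar[i, j] = 1.0 / (np.sqrt(deg[i]) * np.sqrt(deg[j]))
            expected = np.tanh(abar @ h @ w1 + h @ w2 + b)
            np.testing.assert_allclose(gcn_layer(h, g, w1, w2, b), expected,
                                       atol=1e-10)

    def test_shape_mismatch_raises(self, path3_graph):
        with pytest.raises(ValueError):
            gcn_layer(np.ones((3, 2)), path3_graph, np.ones((3, 3)),
                      np.ones((3, 3)), np.zeros(3))


class TestGCNEncode:
    def test_layer_weight_selection(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, 4)
        x = _embedded(g, dim=5)
        params = init_gcn_params(5, width=5, depth=1, seed=2)
        params.input_proj = None  # D == N: identity input level
        params.layer_weights = np.array([0.0, 1.0])
        w1, w2, b = params.layers[0]
        expected = gcn_layer(x.matrix, g, w1, w2, b)
        np.testing.assert_allclose(gcn_encode(x, params).matrix, expected,
                                   atol=1e-12)

    def test_identity_configuration_bypasses_encoder(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, 4)
        x = _embedded(g, dim=5)
        params = init_gcn_params(5, width=5, depth=2, seed=3)
        params.input_proj = None
        params.layer_weights = np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(gcn_encode(x, params).matrix, x.matrix,
                                   atol=1e-12)

    def test_benzene_rows_identical(self):
        g = mv.build_graph(mv.parse_smiles("c1ccccc1"))
        x = _embedded(g, dim=4)
        params = init_gcn_params(4, width=6, depth=3, seed=5)
        p = gcn_encode(x, params).matrix
        assert p.shape == (6, 6)
        np.testing.assert_allclose(p, np.tile(p[0], (6, 1)), atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        params = init_gcn_params(4, width=5, depth=2, seed=6)
        for _ in range(20):
            size = int(rng.integers(2, 8))
            g = random_graph(rng, size)
            x = _embedded(g, dim=4, seed=int(rng.integers(1000)))
            perm = rng.permutation(size)
            g_perm = mv.MolGraph(tokens=g.tokens[perm],
                                 adjacency=g.adjacency[np.ix_(perm, perm)])
            x_perm = EmbeddedMolecule(matrix=x.matrix[perm], graph=g_perm)
            p = gcn_encode(x, params).matrix
            p_perm = gcn_encode(x_perm, params).matrix
            np.testing.assert_allclose(p_perm, p[perm], atol=1e-6)

    def test_row_count_preserved(self):
        rng = np.random.default_rng(3)
        params = init_gcn_params(4, width=7, depth=2, seed=1)
        for size in (1, 2, 5, 9):
            g = random_graph(rng, size)
            x = _embedded(g, dim=4)
            assert gcn_encode(x, params).matrix.shape == (size, 7)


class TestBiLMEncode:
    def test_null_network_gives_zero_features(self):
        g = mv.MolGraph(tokens=[0, 1, 2], adjacency=np.zeros((3, 3)))
        x = _embedded(g, dim=4)
        params = init_bilm_params(4, width=4, depth=1, cell_type="rnn", seed=0)
        params.input_proj = None
        for stack in (params.forward_layers, params.backward_layers):
            stack[0] = (np.zeros_like(stack[0][0]), np.zeros_like(stack[0][1]),
                        np.zeros_like(stack[0][2]))
        params.layer_weights = np.array([0.0, 1.0])
        out = bilm_encode(x, params).matrix
        np.testing.assert_allclose(out, np.zeros((3, 4)), atol=1e-15)

    @pytest.mark.parametrize("cell", ["rnn", "gru", "lstm"])
    def test_direction_symmetry(self, cell):
        """Reversing the atom sequence and swapping forward/backward stacks
        reverses the feature rows."""
        rng = np.random.default_rng(4)
        g = random_graph(rng, 5)
        x = _embedded(g, dim=4)
        params = init_bilm_params(4, width=4, depth=2, cell_type=cell, seed=7)
        swapped = BiLMParams(cell_type=cell,
                             forward_layers=params.backward_layers,
                             backward_layers=params.forward_layers,
                             layer_weights=params.layer_weights,
                             input_proj=params.input_proj)
        g_rev = mv.MolGraph(tokens=g.tokens[::-1].copy(),
                            adjacency=g.adjacency[::-1, ::-1].copy())
        x_rev = EmbeddedMolecule(matrix=x.matrix[::-1].copy(), graph=g_rev)
        p = bilm_encode(x, params).matrix
        p_rev = bilm_encode(x_rev, swapped).matrix
        np.testing.assert_allclose(p_rev, p[::-1], atol=1e-10)

    def test_single_atom_sequence(self):
        g = mv.MolGraph(tokens=[3], adjacency=[[0.0]])
        x = _embedded(g, dim=4)
        params = init_bilm_params(4, width=6, depth=2, cell_type="gru", seed=8)
        assert bilm_encode(x, params).matrix.shape == (1, 6)

    def test_benzene_rows_not_identical(self):
        """The sequential encoder breaks ring symmetry: equal tokens do NOT
        yield equal feature rows, unlike the GCN."""
        g = mv.build_graph(mv.parse_smiles("c1ccccc1"))
        x = _embedded(g, dim=4)
        params = init_bilm_params(4, width=6, depth=2, cell_type="lstm", seed=9)
        p = bilm_encode(x, params).matrix
        spread = np.abs(p - p[0]).max()
        assert spread > 1e-6

    def test_row_count_preserved(self):
        rng = np.random.default_rng(5)
        params = init_bilm_params(4, width=5, depth=1, cell_type="gru", seed=2)
        for size in (1, 3, 7):
            g = random_graph(rng, size)
            x = _embedded(g, dim=4)
            assert bilm_encode(x, params).matrix.shape == (size, 5)
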