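import numpy as np
import pytest

from admetgnn.autodiff import Tensor
from admetgnn.layers import (AttentionHead, GlobalAttentionPool,
                             GraphConvolution, MultiHeadAttention, masked_sum)
from admetgnn.molgraph import BOND_CLASSES, GraphBatch

from .conftest import random_graph
from .reference import attention_head_reference, graph_convolution_reference


class TestAttentionHead:
    def test_single_node_softmax_of_one(self, rng):
        head = AttentionHead(3, 2, rng)
        H = rng.normal(size=(1, 3)).astype(np.float32)
        out = head(Tensor(H), np.array([[1.0]]))
        z = H @ head.W.data
        expected = np.where(z > 0, z, 0.2 * z)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)
        lam = head.attention_matrix(Tensor(H), np.array([[1.0]]))
        np.testing.assert_allclose(lam, [[1.0]])

    def test_identical_rows_give_uniform_attention(self, rng):
        n = 5
        head = AttentionHead(4, 3, rng)
        H = np.tile(rng.normal(size=(1, 4)), (n, 1)).astype(np.float32)
        A = np.ones((n, n))
        lam = head.attention_matrix(Tensor(H), A)
        np.testing.assert_allclose(lam, np.full((n, n), 1 / n), atol=1e-6)

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(2, 7))
            H, A = random_graph(rng, n, 5)
            head = AttentionHead(5, 3, np.random.default_rng(100 + trial))
            got = head(Tensor(H.astype(np.float64)), A).data
            a = np.concatenate([head.a_src.data[:, 0], head.a_dst.data[:, 0]])
            want = attention_head_reference(H.astype(np.float64), A,
                                            head.W.data.astype(np.float64), a)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_rows_are_stochastic_on_molecules(self, rng, diverse_smiles):
        batch = GraphBatch.from_smiles(diverse_smiles)
        head = AttentionHead(batch.H.shape[-1], 4, rng)
        lam = head.attention_matrix(Tensor(batch.H), batch.A_full)
        for b in range(len(batch)):
            n = batch.n_atoms[b]
            np.testing.assert_allclose(lam[b, :n].sum(axis=-1), 1.0, atol=1e-6)
            assert np.all(lam[b, n:] == 0)

    def test_empty_neighborhood_rows_are_zero(self, rng):
        head = AttentionHead(3, 2, rng)
        A = np.zeros((3, 3))
        A[:2, :2] = 1.0                  # node 2 is isolated (padded)
        out = head(Tensor(rng.normal(size=(3, 3))), A)
        assert np.all(out.data[2] == 0)

    def test_shape_mismatch_raises(self, rng):
        head = AttentionHead(3, 2, rng)
        with pytest.raises(ValueError):
            head(Tensor(np.zeros((4, 5))), np.ones((4, 4)))
        with pytest.raises(ValueError):
            head(Tensor(np.zeros((4, 3))), np.ones((3, 3)))


class TestMultiHeadAttention:
    def test_k1_concat_equals_single_head(self, rng):
        mh = MultiHeadAttention(4, 3, 1, "concat", np.random.default_rng(5))
        H, A = random_graph(rng, 4, 4)
        got = mh(Tensor(H[None]), A[None]).data[0]
        want = mh.heads[0](Tensor(H), A).data
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_identical_heads_average_to_single_head(self, rng):
        mh = MultiHeadAttention(4, 3, 3, "average", np.random.default_rng(5))
        for h in mh.heads[1:]:          # copy head-0 parameters into all heads
            h.W.data = mh.heads[0].W.data.copy()
            h.a_src.data = mh.heads[0].a_src.data.copy()
            h.a_dst.data = mh.heads[0].a_dst.data.copy()
        H, A = random_graph(rng, 4, 4)
        got = mh(Tensor(H[None]), A[None]).data[0]
        want = mh.heads[0](Tensor(H), A).data
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_concat_output_width(self, rng):
        mh = MultiHeadAttention(10, 8, 4, "concat", rng)
        assert mh.d_out == 32
        H, A = random_graph(np.random.default_rng(1), 5, 10)
        assert mh(Tensor(H[None]), A[None]).shape == (1, 5, 32)

    def test_fused_path_matches_per_head_loop(self, rng):
        mh = MultiHeadAttention(6, 4, 3, "concat", np.random.default_rng(9))
        H, A = random_graph(rng, 5, 6)
        fused = mh(Tensor(H[None]), A[None]).data[0]
        loop = np.concatenate([h(Tensor(H), A).data for h in mh.heads], axis=-1)
        np.testing.assert_allclose(fused, loop, atol=1e-6)

    def test_bad_config_raises(self, rng):
        with pytest.raises(ValueError):
            MultiHeadAttention(4, 3, 0, "concat", rng)
        with pytest.raises(ValueError):
            MultiHeadAttention(4, 3, 2, "sum", rng)


class TestMaskedSum:
    def test_molecule_rows_match_hand_computation(self):
        # C=CCO: double bond (0,1), singles (1,2), (2,3)
        batch = GraphBatch.from_smiles(["C=CCO"], n_max=6)
        F = 3
        rng = np.random.default_rng(0)
        branches = {k: Tensor(rng.normal(size=(1, 6, F))) for k in BOND_CLASSES}
        out = masked_sum(branches, batch.A_sub).data[0]
        # atom 0: only double; atom 1: double + single; atoms 2,3: single only
        np.testing.assert_allclose(out[0], branches["double"].data[0, 0])
        np.testing.assert_allclose(
            out[1], branches["double"].data[0, 1] + branches["single"].data[0, 1])
        np.testing.assert_allclose(out[2], branches["single"].data[0, 2])
        # padded atoms: zero rows
        assert np.all(out[4:] == 0)

    def test_aromatic_only_atom_takes_aromatic_branch(self):
        batch = GraphBatch.from_smiles(["c1ccccc1"], n_max=7)
        rng = np.random.default_rng(1)
        branches = {k: Tensor(rng.normal(size=(1, 7, 2))) for k in BOND_CLASSES}
        out = masked_sum(branches, batch.A_sub).data[0]
        for j in range(6):
            np.testing.assert_allclose(out[j], branches["aromatic"].data[0, j])

    def test_inconsistent_shapes_raise(self):
        batch = GraphBatch.from_smiles(["CC"], n_max=2)
        branches = {k: Tensor(np.zeros((1, 2, 3))) for k in BOND_CLASSES}
        branches["double"] = Tensor(np.zeros((1, 2, 4)))
        with pytest.raises(ValueError):
            masked_sum(branches, batch.A_sub)


class TestGlobalAttentionPool:
    def test_zero_parameters_give_zero_output(self, rng):
        pool = GlobalAttentionPool(4, 3, rng)
        for p in (pool.W1, pool.W2, pool.b1, pool.b2):
            p.data = np.zeros_like(p.data)
        out = pool(Tensor(rng.normal(size=(2, 5, 4))), np.ones((2, 5)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_single_node_closed_form(self, rng):
        pool = GlobalAttentionPool(4, 3, rng)
        h = rng.normal(size=(1, 1, 4))
        out = pool(Tensor(h), np.ones((1, 1))).data[0]
        gate = 1 / (1 + np.exp(-(h[0, 0] @ pool.W1.data + pool.b1.data)))
        want = gate * (h[0, 0] @ pool.W2.data + pool.b2.data)
        np.testing.assert_allclose(out, want, atol=1e-6)

    def test_permutation_invariance(self, rng):
        pool = GlobalAttentionPool(4, 3, rng)
        H = rng.normal(size=(1, 6, 4))
        mask = np.array([[1, 1, 1, 1, 0, 0]], dtype=float)
        perm = np.array([3, 0, 2, 1, 5, 4])
        a = pool(Tensor(H), mask).data
        b = pool(Tensor(H[:, perm]), mask[:, perm]).data
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_padded_rows_excluded(self, rng):
        pool = GlobalAttentionPool(4, 3, rng)
        H = rng.normal(size=(1, 5, 4))
        mask = np.array([[1, 1, 0, 0, 0]], dtype=float)
        a = pool(Tensor(H), mask).data
        H2 = H.copy()
        H2[0, 2:] = 99.0                 # junk in padded rows must not matter
        b = pool(Tensor(H2), mask).data
        np.testing.assert_allclose(a, b)


class TestGraphConvolution:
    def test_single_node_identity_normalization(self, rng):
        gc = GraphConvolution(3, 2, rng)
        h = rng.normal(size=(1, 1, 3))
        out = gc(Tensor(h), np.ones((1, 1, 1))).data[0, 0]
        hw = h[0, 0] @ gc.W.data
        np.testing.assert_allclose(out, np.where(hw > 0, hw, 0.2 * hw), atol=1e-6)

    def test_matches_edge_loop_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = int(rng.integers(2, 7))
            H, A = random_graph(rng, n, 4)
            gc = GraphConvolution(4, 3, np.random.default_rng(200 + trial))
            got = gc(Tensor(H[None].astype(np.float64)), A[None]).data[0]
            want = graph_convolution_reference(H.astype(np.float64), A,
                                               gc.W.data.astype(np.float64))
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_zero_degree_rows_stay_zero(self, rng):
        gc = GraphConvolution(3, 2, rng)
        A = np.zeros((1, 3, 3))
        A[0, :2, :2] = 1.0
        out = gc(Tensor(rng.normal(size=(1, 3, 3))), A)
        assert np.all(out.data[0, 2] == 0)

    def test_fewer_parameters_than_attention_of_equal_width(self, rng):
        d_in, F = 32, 32
        for K in (1, 2, 4, 8):
            mh = MultiHeadAttention(d_in, F, K, "concat", np.random.default_rng(0))
            gc = GraphConvolution(d_in, F * K, np.random.default_rng(0))
            assert gc.n_parameters < mh.n_parameters
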