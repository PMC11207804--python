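import numpy as np
import pytest

from admetgnn.molgraph import (BOND_CLASSES, CapacityExceededError,
                               FeatureVocabulary, GraphBatch, AtomRecord,
                               SmilesParseError, UnsupportedElementError,
                               build_adjacency_set, encode_atom, featurize,
                               parse_smiles)


class TestParseSmiles:
    @pytest.mark.parametrize("smiles,n_atoms,bonds", [
        ("C", 1, []),
        ("C#N", 2, [("triple", 1)]),
        ("c1ccccc1", 6, [("aromatic", 6)]),
        ("CC", 2, [("single", 1)]),
        ("C=C", 2, [("double", 1)]),
    ])
    def test_atom_and_bond_classes(self, smiles, n_atoms, bonds):
        mol = parse_smiles(smiles)
        assert mol.n_atoms == n_atoms
        for cls, count in bonds:
            assert sum(1 for b in mol.bonds if b[2] == cls) == count

    @pytest.mark.parametrize("bad", ["C(((", "xyz", "", "C1CC"])
    def test_malformed_smiles_raise(self, bad):
        with pytest.raises(SmilesParseError):
            parse_smiles(bad)

    def test_hydrogens_are_implicit(self):
        assert parse_smiles("CO").n_atoms == 2  # methanol: C and O only

    def test_bond_indices_valid(self, diverse_smiles):
        for s in diverse_smiles:
            mol = parse_smiles(s)
            seen = set()
            for i, j, _ in mol.bonds:
                assert 0 <= i < mol.n_atoms and 0 <= j < mol.n_atoms and i != j
                assert frozenset((i, j)) not in seen
                seen.add(frozenset((i, j)))


class TestEncodeAtom:
    def test_feature_length_is_sum_of_blocks(self):
        vocab = FeatureVocabulary()
        assert vocab.block_sizes == (101, 8, 7, 2, 2, 4)
        assert vocab.feature_length == 124

    def test_sp3_carbon_hot_indices(self):
        vocab = FeatureVocabulary()
        atom = AtomRecord(6, 0, "SP3", False, False, "Unspecified")
        vec = encode_atom(atom, vocab)
        assert vec.sum() == 6
        # offsets: Z=6 -> index 5; charge 0 -> 101+3; SP3 -> 109+3;
        # ring No -> 116; aromatic No -> 118; chirality Unspecified -> 120
        assert set(np.flatnonzero(vec)) == {5, 104, 112, 116, 118, 120}

    def test_extreme_charge_bucket(self):
        vocab = FeatureVocabulary()
        vec = encode_atom(AtomRecord(6, 5, "SP3", False, False, "Unspecified"), vocab)
        charge_block = vec[101:109]
        assert charge_block[7] == 1 and charge_block.sum() == 1

    def test_unsupported_element_raises(self):
        with pytest.raises(UnsupportedElementError):
            encode_atom(AtomRecord(102, 0, "SP3", False, False, "Unspecified"))

    def test_unknown_hybridization_maps_to_other(self):
        vec = encode_atom(AtomRecord(6, 0, "SP2D", False, False, "Unspecified"))
        hyb_block = vec[109:116]
        assert hyb_block[6] == 1


class TestAdjacencySet:
    def test_ethane(self):
        A_full, A_sub = build_adjacency_set(parse_smiles("CC"), 2)
        expected = np.ones((2, 2))
        assert np.array_equal(A_full, expected)
        assert np.array_equal(A_sub["single"], expected)
        for cls in ("double", "triple", "aromatic"):
            assert not A_sub[cls].any()

    def test_propyne_triple_submatrix(self):
        # CC#C: triple bond between atoms 1 and 2; atom 0 not in substructure
        _, A_sub = build_adjacency_set(parse_smiles("CC#C"), 3)
        T = A_sub["triple"]
        assert T[1, 2] == T[2, 1] == T[1, 1] == T[2, 2] == 1
        assert not T[0, :].any() and not T[:, 0].any()

    def test_capacity_exceeded(self):
        with pytest.raises(CapacityExceededError, match="c1ccccc1"):
            build_adjacency_set(parse_smiles("c1ccccc1"), 5)

    def test_symmetry_all_matrices(self, diverse_smiles):
        for s in diverse_smiles:
            g = featurize(s, n_max=30)
            assert np.array_equal(g.A_full, g.A_full.T)
            for cls in BOND_CLASSES:
                assert np.array_equal(g.A_sub[cls], g.A_sub[cls].T)

    def test_full_is_union_of_substructures(self, diverse_smiles):
        for s in diverse_smiles:
            g = featurize(s, n_max=30)
            off = ~np.eye(30, dtype=bool)
            union = np.zeros((30, 30), dtype=bool)
            for cls in BOND_CLASSES:
                union |= g.A_sub[cls].astype(bool)
            assert np.array_equal(g.A_full.astype(bool) & off, union & off)

    def test_diagonal_is_participation_indicator(self, diverse_smiles):
        for s in diverse_smiles:
            mol = parse_smiles(s)
            _, A_sub = build_adjacency_set(mol, mol.n_atoms)
            for cls in BOND_CLASSES:
                incident = np.zeros(mol.n_atoms, dtype=bool)
                for i, j, k in mol.bonds:       # brute-force scan of bond list
                    if k == cls:
                        incident[i] = incident[j] = True
                assert np.array_equal(np.diag(A_sub[cls]).astype(bool), incident)


class TestFeaturize:
    def test_padding_rows_are_zero(self):
        g = featurize("CC", n_max=5)
        assert g.H.shape == (5, 124)
        assert not g.H[2:].any()
        assert not g.A_full[2:].any() and not g.A_full[:, 2:].any()

    def test_full_diag_self_loops_only_on_real_atoms(self):
        g = featurize("CC", n_max=5)
        assert np.array_equal(np.diag(g.A_full), [1, 1, 0, 0, 0])

    def test_real_rows_have_six_ones(self, diverse_smiles):
        for s in diverse_smiles:
            g = featurize(s, n_max=30)
            assert np.array_equal(g.H[:g.n_atoms].sum(axis=1),
                                  np.full(g.n_atoms, 6.0))
            assert not g.H[g.n_atoms:].any()

    def test_padding_neutrality(self, diverse_smiles):
        for s in diverse_smiles:
            n = parse_smiles(s).n_atoms
            tight, loose = featurize(s, n_max=n), featurize(s, n_max=n + 10)
            assert np.array_equal(tight.H, loose.H[:n])
            assert np.array_equal(tight.A_full, loose.A_full[:n, :n])
            for cls in BOND_CLASSES:
                assert np.array_equal(tight.A_sub[cls], loose.A_sub[cls][:n, :n])

    def test_deterministic(self):
        a, b = featurize("CC(=O)Oc1ccccc1", n_max=15), featurize("CC(=O)Oc1ccccc1", n_max=15)
        assert np.array_equal(a.H, b.H) and np.array_equal(a.A_full, b.A_full)

    def test_same_molecule_different_traversal(self):
        a, b = featurize("CCO", n_max=3), featurize("OCC", n_max=3)
        perm = [2, 1, 0]  # OCC emits atoms in reverse order
        assert np.array_equal(a.H, b.H[perm])
        assert np.array_equal(a.A_full, b.A_full[np.ix_(perm, perm)])


class TestGraphBatch:
    def test_node_mask(self, benzene_batch):
        assert benzene_batch.node_mask.shape == (3, 8)
        assert benzene_batch.node_mask.sum(axis=1).tolist() == [6, 3, 4]

    def test_save_load_roundtrip(self, benzene_batch, tmp_path):
        path = tmp_path / "batch.npz"
        benzene_batch.save(path)
        loaded = GraphBatch.load(path)
        assert np.array_equal(loaded.H, benzene_batch.H)
        assert np.array_equal(loaded.A_full, benzene_batch.A_full)
        for cls in BOND_CLASSES:
            assert np.array_equal(loaded.A_sub[cls], benzene_batch.A_sub[cls])
        assert loaded.smiles == benzene_batch.smiles
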