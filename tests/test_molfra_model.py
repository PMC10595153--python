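"""Stage-by-stage and end-to-end behavior of the fragment-pair network."""

import numpy as np
import pytest
from rdkit import Chem

from fragsol.chem_io import smiles_to_graph
from fragsol.molfra_model import (
    AtomStateSet,
    CheckpointMismatchError,
    ConfigError,
    FragmentEmbedding,
    ModelConfig,
    MoleculeEmbedding,
    MolFraNetwork,
    compile_molecule,
)

F = 12  # hidden width of the shared test network


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestInitEmbeddings:
    def test_single_atom_fragment_shape(self, tiny_net):
        s = tiny_net.init_embeddings(smiles_to_graph("C"))
        assert s.states.shape == (1, F)

    def test_output_width_for_any_molecule(self, tiny_net, aspirin):
        assert tiny_net.init_embeddings(aspirin).states.shape == (13, F)

    def test_identical_atoms_get_identical_states(self, tiny_net):
        s = tiny_net.init_embeddings(smiles_to_graph("CCCC"))
        # the two interior CH2 carbons share a feature vector
        np.testing.assert_array_equal(s.states[1], s.states[2])

    def test_feature_width_mismatch_is_config_error(self, tiny_net, ethanol):
        bad = smiles_to_graph("CCO")
        bad.atom_features = bad.atom_features[:, :30]
        with pytest.raises(ConfigError):
            tiny_net.init_embeddings(bad)


class TestAtomAttentionLayer:
    def test_singleton_neighborhood_weight_is_one(self):
        net = MolFraNetwork(ModelConfig(hidden_width=6, seed=2), dtype=np.float64)
        g = smiles_to_graph("CC")
        states = AtomStateSet(np.random.default_rng(0).standard_normal((2, 6)), layer=1)
        ctx = net.atom_attention_layer(states, g, layer=1)
        # each atom's only neighbor gets softmax weight 1: C_t = elu(W a_i)
        W = net.params["atom1/W"].data
        expected = np.stack(
            [np.where((states.states[1] @ W) > 0, states.states[1] @ W,
                      np.exp(np.minimum(states.states[1] @ W, 0)) - 1),
             np.where((states.states[0] @ W) > 0, states.states[0] @ W,
                      np.exp(np.minimum(states.states[0] @ W, 0)) - 1)]
        )
        np.testing.assert_allclose(ctx, expected, atol=1e-12)

    def test_zero_weights_give_zero_context(self, benzene):
        net = MolFraNetwork(ModelConfig(hidden_width=6, seed=2), dtype=np.float64)
        net.params["atom1/W"].data[:] = 0.0
        net.params["atom1/s"].data[:] = 0.0
        states = AtomStateSet(np.random.default_rng(1).standard_normal((6, 6)), layer=1)
        ctx = net.atom_attention_layer(states, benzene, layer=1)
        np.testing.assert_allclose(ctx, 0.0, atol=1e-12)  # elu(0) = 0

    def test_isolated_atom_receives_zero_context(self, tiny_net):
        g = smiles_to_graph("C")
        states = AtomStateSet(np.ones((1, F)), layer=1)
        ctx = tiny_net.atom_attention_layer(states, g, layer=1)
        np.testing.assert_allclose(ctx, 0.0)

    def test_attention_weights_sum_to_one_each_layer(self, tiny_net, aspirin):
        units = compile_molecule(aspirin)
        pair_mol = np.zeros(units.n_pairs, dtype=np.intp)
        tiny_net.forward_units(units, pair_mol, 1, record_attention=True)
        layers = tiny_net._last_attention
        assert len(layers) == tiny_net.cfg.atom_layers + tiny_net.cfg.mol_layers
        for alpha, seg, n in layers:
            sums = np.zeros(n)
            np.add.at(sums, seg, alpha)
            occupied = np.bincount(seg, minlength=n) > 0
            np.testing.assert_allclose(sums[occupied], 1.0, atol=1e-6)


class TestGruUpdate:
    def test_output_shape_and_determinism(self, tiny_net):
        prev = AtomStateSet(np.random.default_rng(3).standard_normal((4, F)), layer=1)
        ctx = np.random.default_rng(4).standard_normal((4, F))
        out1 = tiny_net.gru_update(prev, ctx)
        out2 = tiny_net.gru_update(prev, ctx)
        assert out1.states.shape == (4, F)
        np.testing.assert_array_equal(out1.states, out2.states)

    def test_shape_mismatch_rejected(self, tiny_net):
        prev = AtomStateSet(np.zeros((4, F)), layer=1)
        with pytest.raises(ValueError, match="mismatch"):
            tiny_net.gru_update(prev, np.zeros((3, F)))

    def test_zero_input_closed_form(self, tiny_net):
        # at zero state and zero context the cell value depends only on biases:
        # h' = (1 - sigmoid(bz)) * tanh(bh)
        prev = AtomStateSet(np.zeros((5, F)), layer=0)
        out = tiny_net.gru_update(prev, np.zeros((5, F)))
        bz = tiny_net.params["atom0/gru/bz"].data
        bh = tiny_net.params["atom0/gru/bh"].data
        expected = (1.0 - sigmoid(bz)) * np.tanh(bh)
        for row in out.states:
            np.testing.assert_allclose(row, expected, atol=1e-12)


class TestSupernode:
    def test_opposite_states_average_to_zero(self, tiny_net):
        e = np.random.default_rng(5).standard_normal(F)
        sg = tiny_net.build_supernode_graph(AtomStateSet(np.stack([e, -e])))
        np.testing.assert_allclose(sg.node_states[0], 0.0, atol=1e-12)

    def test_single_atom_supernode_copies_state(self, tiny_net):
        v = np.random.default_rng(6).standard_normal(F)
        sg = tiny_net.build_supernode_graph(AtomStateSet(v[None, :]))
        np.testing.assert_allclose(sg.node_states[0], v)

    def test_equal_states_mean_is_that_state(self, tiny_net):
        v = np.random.default_rng(7).standard_normal(F)
        sg = tiny_net.build_supernode_graph(AtomStateSet(np.tile(v, (6, 1))))
        np.testing.assert_allclose(sg.node_states[0], v, atol=1e-12)

    def test_empty_fragment_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net.build_supernode_graph(AtomStateSet(np.zeros((0, F))))


class TestReadout:
    def test_embedding_width(self, tiny_net):
        states = AtomStateSet(np.random.default_rng(8).standard_normal((4, F)))
        y = tiny_net.readout_fragment(tiny_net.build_supernode_graph(states))
        assert y.vector.shape == (F,)

    def test_atom_permutation_invariance(self, tiny_net):
        states = np.random.default_rng(9).standard_normal((5, F))
        perm = np.random.default_rng(10).permutation(5)
        y1 = tiny_net.readout_fragment(
            tiny_net.build_supernode_graph(AtomStateSet(states))
        )
        y2 = tiny_net.readout_fragment(
            tiny_net.build_supernode_graph(AtomStateSet(states[perm]))
        )
        np.testing.assert_allclose(y1.vector, y2.vector, atol=1e-10)

    def test_zero_mol_weights_reduce_to_gru_of_supernode(self):
        net = MolFraNetwork(ModelConfig(hidden_width=6, mol_layers=1, seed=3), dtype=np.float64)
        net.params["mol0/W"].data[:] = 0.0
        net.params["mol0/s"].data[:] = 0.0
        v = np.random.default_rng(11).standard_normal(6)
        y = net.readout_fragment(net.build_supernode_graph(AtomStateSet(v[None, :])))
        # zero projections make the context elu(0)=0; embedding = GRU(x_s, 0)
        bz = net.params["mol0/gru/bz"].data
        Uz = net.params["mol0/gru/Uz"].data
        br = net.params["mol0/gru/br"].data
        Ur = net.params["mol0/gru/Ur"].data
        bh = net.params["mol0/gru/bh"].data
        Uh = net.params["mol0/gru/Uh"].data
        z = sigmoid(v @ Uz + bz)
        r = sigmoid(v @ Ur + br)
        n = np.tanh((r * v) @ Uh + bh)
        np.testing.assert_allclose(y.vector, (1 - z) * n + z * v, atol=1e-12)


class TestFusionAndHead:
    def test_fuse_identity_and_commutativity(self, tiny_net):
        a = FragmentEmbedding(np.arange(F, dtype=float))
        zero = FragmentEmbedding(np.zeros(F))
        np.testing.assert_array_equal(tiny_net.fuse_pair(a, zero).vector, a.vector)
        b = FragmentEmbedding(np.random.default_rng(12).standard_normal(F))
        np.testing.assert_array_equal(
            tiny_net.fuse_pair(a, b).vector, tiny_net.fuse_pair(b, a).vector
        )
        np.testing.assert_array_equal(tiny_net.fuse_pair(zero, zero).vector, 0.0)

    def test_fuse_width_mismatch(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net.fuse_pair(
                FragmentEmbedding(np.zeros(F)), FragmentEmbedding(np.zeros(F + 1))
            )

    def test_average_pairs_algebra(self, tiny_net):
        v = np.random.default_rng(13).standard_normal(F)
        one = [MoleculeEmbedding(v)]
        np.testing.assert_array_equal(tiny_net.average_pairs(one).vector, v)
        triple = [MoleculeEmbedding(v), MoleculeEmbedding(2 * v), MoleculeEmbedding(-v)]
        fwd = tiny_net.average_pairs(triple).vector
        rev = tiny_net.average_pairs(triple[::-1]).vector
        np.testing.assert_allclose(fwd, rev)
        np.testing.assert_allclose(
            tiny_net.average_pairs(
                [MoleculeEmbedding(v), MoleculeEmbedding(-v)]
            ).vector,
            0.0,
            atol=1e-12,
        )
        with pytest.raises(ValueError):
            tiny_net.average_pairs([])

    def test_head_is_affine(self, tiny_net):
        zero = tiny_net.predict_head(MoleculeEmbedding(np.zeros(F)))
        assert zero == 0.0  # zero-initialized bias
        y = np.random.default_rng(14).standard_normal(F)
        h1 = tiny_net.predict_head(MoleculeEmbedding(y))
        h2 = tiny_net.predict_head(MoleculeEmbedding(2 * y))
        assert h2 - zero == pytest.approx(2 * (h1 - zero), rel=1e-9)


class TestForward:
    def test_smiles_rewriting_invariance(self, tiny_net):
        p1 = tiny_net.forward(smiles_to_graph("CCO"))
        p2 = tiny_net.forward(smiles_to_graph("OCC"))
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_random_rewritings_of_larger_molecule(self, tiny_net):
        smi = "CC(=O)Oc1ccccc1C(=O)O"
        mol = Chem.MolFromSmiles(smi)
        base = tiny_net.forward(smiles_to_graph(smi))
        for root in range(0, mol.GetNumAtoms(), 4):
            alt = Chem.MolToSmiles(mol, canonical=False, rootedAtAtom=root)
            assert tiny_net.forward(smiles_to_graph(alt)) == pytest.approx(base, abs=1e-8)

    def test_ring_molecule_falls_back_to_null_path(self, tiny_net, benzene):
        assert tiny_net.forward(benzene) == tiny_net.null_fragment_forward(benzene)

    def test_single_atom_fragment_and_null_paths_agree(self, tiny_net):
        g = smiles_to_graph("C")
        assert tiny_net.forward(g) == tiny_net.null_fragment_forward(g)

    def test_evaluation_mode_deterministic(self, tiny_net, aspirin):
        assert tiny_net.forward(aspirin) == tiny_net.forward(aspirin)

    def test_null_path_performs_no_pair_enumeration(self, benzene):
        net = MolFraNetwork(ModelConfig(hidden_width=6, seed=4))
        net.null_fragment_forward(benzene)
        assert net.stats["pair_enumerations"] == 0

    def test_batched_forward_matches_single(self, tiny_net):
        smis = ["CCO", "CC(=O)Oc1ccccc1C(=O)O", "c1ccccc1", "CCNCC"]
        units = [compile_molecule(smiles_to_graph(s)) for s in smis]
        batched = tiny_net.predict_batch(units).data
        singles = [tiny_net.forward(smiles_to_graph(s)) for s in smis]
        np.testing.assert_allclose(batched, singles, atol=1e-9)

    def test_parameter_count_independent_of_molecule_size(self, tiny_net):
        n0 = tiny_net.n_parameters
        tiny_net.forward(smiles_to_graph("CCCCCCCCCCCC"))
        tiny_net.forward(smiles_to_graph("C"))
        assert tiny_net.n_parameters == n0


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, ethanol):
        net = MolFraNetwork(ModelConfig(hidden_width=8, seed=5))
        before = net.forward(ethanol)
        p = tmp_path / "ckpt.json"
        net.save(p)
        loaded = MolFraNetwork.load(p)
        assert loaded.forward(ethanol) == pytest.approx(before, abs=1e-6)

    def test_feature_digest_mismatch_refused(self, tmp_path):
        from fragsol.chem_io import FeatureConfig

        net = MolFraNetwork(ModelConfig(hidden_width=8, seed=5))
        p = tmp_path / "ckpt.json"
        net.save(p)
        other = FeatureConfig(stereo_vocab=("STEREONONE", "STEREOZ", "STEREOE", "STEREOANY"))
        with pytest.raises(CheckpointMismatchError):
            MolFraNetwork.load(p, feature_cfg=other)


def test_network_gradient_matches_finite_differences():
    """End-to-end MSE gradient check on a tiny molecule at float64."""
    from fragsol._autodiff import Tensor

    net = MolFraNetwork(ModelConfig(hidden_width=4, seed=6), dtype=np.float64)
    units = compile_molecule(smiles_to_graph("CCO"))
    pair_mol = np.zeros(units.n_pairs, dtype=np.intp)

    def loss_value():
        pred = net.forward_units(units, pair_mol, 1)
        return float(((pred - 1.5) * (pred - 1.5)).mean().data)

    net.zero_grad()
    pred = net.forward_units(units, pair_mol, 1)
    loss = (pred - 1.5) * (pred - 1.5)
    loss.mean().backward()

    eps = 1e-6
    for name in ["atom0/W", "atom1/gru/Uz", "mol0/s", "head/W", "neighbor_init/W"]:
        p = net.params[name]
        flat = p.data.ravel()
        for i in np.linspace(0, flat.size - 1, 5, dtype=int):
            orig = flat[i]
            flat[i] = orig + eps
            hi = loss_value()
            flat[i] = orig - eps
            lo = loss_value()
            flat[i] = orig
            num = (hi - lo) / (2 * eps)
            got = p.grad.ravel()[i] if p.grad is not None else 0.0
            assert got == pytest.approx(num, rel=1e-4, abs=1e-7), name
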