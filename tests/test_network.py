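import numpy as np
import pytest

from revfold.core import ModelConfig
from revfold.network import (
    all_layer_params,
    apply_chain_constraint,
    design,
    embed_coords_adjoint,
    embed_inputs,
    fold,
    gcn_block,
    init_weights,
    invert_trajectory,
    layer_params,
    load_checkpoint,
    min_chain_length,
    project_coords,
    recover_sequence_adjoint,
    save_checkpoint,
    symmetric_unet,
    verlet_backward,
    verlet_forward,
)
from revfold.graph_ops import edge_weights, graph_laplacian, pairwise_distances


class TestEmbeddings:
    def test_zero_input_zero_latent(self, rng):
        th = rng.standard_normal((8, 40))
        assert np.all(embed_inputs(np.zeros((40, 5)), th) == 0)
        assert np.all(recover_sequence_adjoint(np.zeros((8, 5)), th) == 0)

    def test_identity_embedding(self):
        th = np.eye(40)
        x = np.arange(40.0 * 3).reshape(40, 3)
        np.testing.assert_array_equal(embed_inputs(x, th), x)

    def test_embed_then_adjoint_is_gram_product(self, rng):
        th = rng.standard_normal((16, 40))
        x = rng.standard_normal((40, 7))
        got = recover_sequence_adjoint(embed_inputs(x, th), th)
        np.testing.assert_allclose(got, th.T @ th @ x, atol=1e-6)

    def test_sequence_adjoint_inner_product_identity(self, rng):
        th = rng.standard_normal((16, 40))
        x = rng.standard_normal((40, 6))
        y = rng.standard_normal((16, 6))
        lhs = np.sum(embed_inputs(x, th) * y)
        rhs = np.sum(x * recover_sequence_adjoint(y, th))
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_coordinate_adjoint_inner_product_identity(self, rng):
        th = rng.standard_normal((16, 3))
        Y = rng.standard_normal((16, 9))
        X = rng.standard_normal((3, 9))
        lhs = np.sum(project_coords(Y, th) * X)
        rhs = np.sum(Y * embed_coords_adjoint(X, th))
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_coordinate_embedding_homogeneous(self, rng):
        th = rng.standard_normal((8, 3))
        X = rng.standard_normal((3, 4))
        np.testing.assert_allclose(embed_coords_adjoint(2 * X, th),
                                   2 * embed_coords_adjoint(X, th))

    def test_orthogonal_embedding_inverted_by_adjoint(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((40, 40)))
        x = rng.standard_normal((40, 5))
        np.testing.assert_allclose(
            recover_sequence_adjoint(embed_inputs(x, q), q), x, atol=1e-10)


class TestChainConstraint:
    def test_fixed_point_at_target_spacing(self, rng):
        steps = rng.standard_normal((3, 9))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=0)
        X = np.concatenate([np.zeros((3, 1)), np.cumsum(steps, axis=1)], axis=1)
        np.testing.assert_allclose(apply_chain_constraint(X, 3.8), X, atol=1e-9)

    def test_collinear_chain_rescaled(self):
        X = np.vstack([np.arange(5) * 7.6, np.zeros(5), np.zeros(5)])
        out = apply_chain_constraint(X, 3.8)
        np.testing.assert_allclose(out[0], np.arange(5) * 3.8, atol=1e-12)
        np.testing.assert_allclose(out[1:], 0.0)

    def test_random_chain_spacing_exact(self, rng):
        X = rng.standard_normal((3, 20)) * 10
        out = apply_chain_constraint(X, 3.8)
        d = np.linalg.norm(np.diff(out, axis=1), axis=0)
        np.testing.assert_allclose(d, 3.8, atol=1e-6)
        # directions preserved
        u_in = np.diff(X, axis=1)
        u_in /= np.linalg.norm(u_in, axis=0)
        u_out = np.diff(out, axis=1)
        u_out /= np.linalg.norm(u_out, axis=0)
        np.testing.assert_allclose(u_in, u_out, atol=1e-9)

    def test_coincident_positions_rejected(self):
        X = np.zeros((3, 3))
        with pytest.raises(ValueError, match="coincident"):
            apply_chain_constraint(X, 3.8)

    def test_projection_with_constraint(self, rng):
        th = rng.standard_normal((16, 3))
        YT = rng.standard_normal((16, 12))
        X = project_coords(YT, th, constrain=True, spacing=3.8)
        d = np.linalg.norm(np.diff(X, axis=1), axis=0)
        np.testing.assert_allclose(d, 3.8, atol=1e-6)


def _laplacian_for(Y, alpha=10.0):
    return graph_laplacian(edge_weights(pairwise_distances(Y), alpha))


class TestGcnBlock:
    def test_zero_input_zero_output(self):
        Y = np.zeros((4, 6))
        out = gcn_block(Y, np.zeros((6, 6)), np.zeros((4, 4, 3)), omega=1)
        np.testing.assert_array_equal(out, 0.0)

    def test_single_residue_chain(self, rng):
        Y = rng.standard_normal((4, 1))
        K = rng.standard_normal((4, 4, 3))
        out = gcn_block(Y, np.zeros((1, 1)), K, omega=1, normalize=False)
        # at n=1 the convolution reduces to the center tap
        expected = Y + np.maximum(K[:, :, 1] @ Y, 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        nf, n, k = 5, 9, 3
        Y = rng.standard_normal((nf, n))
        K = rng.standard_normal((nf, nf, k))
        L = _laplacian_for(Y)
        got = gcn_block(Y, L, K, omega=1, normalize=False)

        conv = np.zeros((nf, n))
        for o in range(nf):
            for i in range(nf):
                for t in range(k):
                    for p in range(n):
                        src = p + t - k // 2
                        if 0 <= src < n:
                            conv[o, p] += K[o, i, t] * Y[i, src]
        z = conv + Y @ L
        expected = Y + np.maximum(z, 0.0)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_wrong_laplacian_shape_rejected(self, rng):
        with pytest.raises(ValueError, match="Laplacian"):
            gcn_block(np.ones((4, 6)), np.zeros((5, 5)), np.zeros((4, 4, 3)), 1)


class TestSymmetricUnet:
    def test_shape_preserved_across_lengths(self, rng):
        cfg = ModelConfig(nf=8, T=1, nLevels=3, seed=0)
        w = init_weights(cfg)
        lw = layer_params(w, 0, cfg)
        for n in (8, 9, 17):
            Y = rng.standard_normal((8, n))
            assert symmetric_unet(Y, lw, cfg).shape == (8, n)

    def test_zero_input_zero_output(self):
        cfg = ModelConfig(nf=8, T=1, nLevels=2, seed=0)
        w = init_weights(cfg)
        out = symmetric_unet(np.zeros((8, 10)), layer_params(w, 0, cfg), cfg)
        np.testing.assert_array_equal(out, 0.0)

    def test_too_short_chain_reports_minimum(self):
        cfg = ModelConfig(nf=8, T=1, nLevels=4, seed=0)
        w = init_weights(cfg)
        assert min_chain_length(cfg) == 8
        with pytest.raises(ValueError, match=">= 8"):
            symmetric_unet(np.ones((8, 5)), layer_params(w, 0, cfg), cfg)

    def test_strict_mode_dissipative(self, rng):
        cfg = ModelConfig(nf=8, T=1, strict_symmetric=True, seed=1)
        w = init_weights(cfg)
        lw = layer_params(w, 0, cfg)
        for _ in range(100):
            Y = rng.standard_normal((8, 12))
            assert np.sum(Y * symmetric_unet(Y, lw, cfg)) <= 1e-10


class TestVerlet:
    def test_zero_force_free_motion_from_rest(self):
        cfg = ModelConfig(nf=4, T=3, nLevels=2, seed=0)
        w = {k: np.zeros_like(v) for k, v in init_weights(cfg).items()}
        Y0 = np.arange(4.0 * 8).reshape(4, 8)
        YT, states = verlet_forward(Y0, all_layer_params(w, cfg), cfg.h, cfg)
        for s in states:
            np.testing.assert_array_equal(s, Y0)
        Yb, back = verlet_backward(Y0, all_layer_params(w, cfg), cfg.h, cfg)
        np.testing.assert_array_equal(Yb, Y0)

    def test_single_step_formula(self, rng):
        cfg = ModelConfig(nf=8, T=1, nLevels=2, seed=2, h=0.3)
        w = init_weights(cfg)
        Y0 = rng.standard_normal((8, 10))
        layers = all_layer_params(w, cfg)
        YT, _ = verlet_forward(Y0, layers, cfg.h, cfg)
        f0 = symmetric_unet(Y0, layers[0], cfg)
        np.testing.assert_allclose(YT, Y0 + 0.3**2 * f0, atol=1e-12)

    def test_zero_time_step_is_identity(self, rng):
        cfg = ModelConfig(nf=8, T=4, nLevels=2, seed=2, h=0.0)
        w = init_weights(cfg)
        Y0 = rng.standard_normal((8, 10))
        YT, _ = verlet_forward(Y0, all_layer_params(w, cfg), cfg.h, cfg)
        np.testing.assert_array_equal(YT, Y0)

    def test_backward_reconstructs_forward_trajectory(self, rng):
        cfg = ModelConfig(nf=8, T=5, nLevels=2, seed=4)
        w = init_weights(cfg)
        layers = all_layer_params(w, cfg)
        Y0 = rng.standard_normal((8, 16))
        _, states = verlet_forward(Y0, layers, cfg.h, cfg)
        rec = invert_trajectory(states[-1], states[-2], layers, cfg.h, cfg)
        for got, want in zip(rec, states):
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_inversion_rejected_for_resnet_mode(self, rng):
        cfg = ModelConfig(nf=8, T=2, nLevels=2, seed=4, resnet=True)
        w = init_weights(cfg)
        Y = rng.standard_normal((8, 12))
        with pytest.raises(ValueError, match="reversible"):
            invert_trajectory(Y, Y, all_layer_params(w, cfg), cfg.h, cfg)


class TestEndToEnd:
    def test_fold_contract(self, toy_record, tiny_config):
        w = init_weights(tiny_config)
        X = fold(toy_record, w, tiny_config)
        assert X.shape == (3, 4)
        d = np.linalg.norm(np.diff(X, axis=1), axis=0)
        np.testing.assert_allclose(d, 3.8, atol=1e-6)
        np.testing.assert_array_equal(X, fold(toy_record, w, tiny_config))

    def test_design_contract(self, toy_record, tiny_config):
        w = init_weights(tiny_config)
        onehot, pssm = design(toy_record.coords, w, tiny_config)
        np.testing.assert_allclose(pssm.sum(axis=0), 1.0, atol=1e-6)
        np.testing.assert_array_equal(onehot.sum(axis=0), 1.0)
        again = design(toy_record.coords, w, tiny_config)
        np.testing.assert_array_equal(onehot, again[0])
        np.testing.assert_array_equal(pssm, again[1])

    def test_design_translation_invariant(self, toy_record, tiny_config):
        w = init_weights(tiny_config)
        base = design(toy_record.coords, w, tiny_config)
        shifted = design(toy_record.coords + np.array([[5.0], [-3.0], [2.0]]),
                         w, tiny_config)
        np.testing.assert_allclose(base[1], shifted[1], atol=1e-9)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, tiny_config):
        w = init_weights(tiny_config)
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, w, tiny_config)
        w2, cfg2 = load_checkpoint(path)
        assert cfg2 == tiny_config
        for k in w:
            np.testing.assert_array_equal(w[k], w2[k])

    def test_mismatched_weights_rejected(self, tmp_path, tiny_config):
        w = init_weights(tiny_config)
        other = ModelConfig(nf=16, T=2, nLevels=2, seed=3)
        path = tmp_path / "bad.ckpt"
        save_checkpoint(path, w, other)   # wrong config for these arrays
        with pytest.raises(ValueError):
            load_checkpoint(path)
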