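import numpy as np
import pytest

from revfold.core import ModelConfig
from revfold.graph_ops import pairwise_distances
from revfold.losses import (
    EVAL_CUTOFF,
    TRAIN_CUTOFF,
    build_distance_mask,
    design_loss,
    fold_loss,
    total_objective,
    tv_regularization,
)
from revfold.network import init_weights


def collinear_chain(n, spacing=3.8):
    return np.vstack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])


class TestDistanceMask:
    def test_complete_mask_counts_off_diagonal(self):
        D = pairwise_distances(collinear_chain(4))
        m = build_distance_mask(D, np.ones(4, bool), np.inf)
        assert m.n_M == 12
        np.testing.assert_array_equal(m.M, m.M.T)
        assert np.all(np.diag(m.M) == 0)

    def test_unobserved_residue_removes_row_and_column(self):
        D = pairwise_distances(collinear_chain(4))
        mask = np.array([True, False, True, True])
        assert build_distance_mask(D, mask, np.inf).n_M == 6

    def test_cutoff_keeps_local_pairs_only(self):
        # collinear chain at 3.8 Å spacing: pairs |i-j| <= 2 within 7.6 Å
        D = pairwise_distances(collinear_chain(10))
        m = build_distance_mask(D, np.ones(10, bool), 7.6)
        # enumeration oracle
        expected = sum(1 for i in range(10) for j in range(10)
                       if i != j and abs(i - j) * 3.8 <= 7.6)
        assert m.n_M == expected == 34

    def test_cutoff_constants(self):
        assert TRAIN_CUTOFF == pytest.approx(26.6)
        assert EVAL_CUTOFF == pytest.approx(22.8)


class TestFoldLoss:
    def test_identical_structures_zero(self, rng):
        X = rng.standard_normal((3, 8)) * 5
        m = build_distance_mask(pairwise_distances(X), np.ones(8, bool), np.inf)
        loss, drmsd = fold_loss(X, X, m)
        assert loss == 0.0 and drmsd == 0.0

    def test_rigid_motion_invariance(self, rng):
        X = rng.standard_normal((3, 10)) * 5
        m = build_distance_mask(pairwise_distances(X), np.ones(10, bool), np.inf)
        for _ in range(100):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            moved = q @ X + rng.standard_normal((3, 1)) * 10
            loss, _ = fold_loss(moved, X, m)
            assert loss < 1e-9

    def test_reflection_invariance(self, rng):
        X = rng.standard_normal((3, 10)) * 5
        m = build_distance_mask(pairwise_distances(X), np.ones(10, bool), np.inf)
        mirrored = X * np.array([[-1.0], [1.0], [1.0]])
        loss, _ = fold_loss(mirrored, X, m)
        assert loss < 1e-9

    def test_three_residue_hand_value(self):
        # native collinear at 3.8 Å, prediction at 4.8 Å: the four ordered
        # adjacent pairs differ by 1 Å and the two ordered end pairs by 2 Å,
        # so the mean masked squared difference is (4·1² + 2·2²)/6 = 2 Å²
        native = collinear_chain(3, 3.8)
        pred = collinear_chain(3, 4.8)
        m = build_distance_mask(pairwise_distances(native), np.ones(3, bool), np.inf)
        loss, drmsd = fold_loss(pred, native, m)
        assert loss == pytest.approx(2.0, abs=1e-12)
        assert drmsd == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_empty_mask_rejected(self):
        X = collinear_chain(3)
        m = build_distance_mask(pairwise_distances(X), np.zeros(3, bool), np.inf)
        with pytest.raises(ValueError, match="mask"):
            fold_loss(X, X, m)


class TestDesignLoss:
    def test_identical_distributions_zero(self, rng):
        p = rng.dirichlet(np.ones(20), size=5).T
        kl_pssm, kl_seq = design_loss(p, p, p, p, np.ones(5, bool))
        assert kl_pssm == pytest.approx(0.0, abs=1e-7)
        assert kl_seq == pytest.approx(0.0, abs=1e-7)

    def test_two_term_hand_value(self):
        true = np.zeros((20, 1))
        true[0], true[1] = 0.5, 0.5
        pred = np.zeros((20, 1))
        pred[0], pred[1] = 0.25, 0.75
        kl_pssm, _ = design_loss(pred, true, pred, true, np.ones(1, bool))
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert kl_pssm == pytest.approx(expected, abs=1e-5)
        assert kl_pssm == pytest.approx(0.14384, abs=1e-4)

    def test_uniform_vs_onehot_is_log20(self):
        true = np.zeros((20, 3))
        true[4] = 1.0
        uniform = np.full((20, 3), 1 / 20)
        _, kl_seq = design_loss(uniform, true, uniform, true, np.ones(3, bool))
        assert kl_seq == pytest.approx(np.log(20), abs=1e-5)

    def test_nonnegative(self, rng):
        for _ in range(20):
            t = rng.dirichlet(np.ones(20), size=4).T
            p = rng.dirichlet(np.ones(20), size=4).T
            kl_pssm, kl_seq = design_loss(p, t, p, t, np.ones(4, bool))
            assert kl_pssm >= 0 and kl_seq >= 0

    def test_invalid_distribution_rejected(self):
        bad = np.full((20, 2), 0.5)
        good = np.full((20, 2), 1 / 20)
        with pytest.raises(ValueError, match="sum to 1"):
            design_loss(bad, good, good, good, np.ones(2, bool))

    def test_fully_masked_pssm_columns_excluded(self):
        true = np.full((20, 3), 1 / 20)
        true[:, 1] = 0.0          # fully masked position in the source data
        pred = np.full((20, 3), 1 / 20)
        kl_pssm, _ = design_loss(pred, true, pred,
                                 np.where(np.arange(20)[:, None] == 0, 1.0,
                                          np.zeros((20, 3))),
                                 np.ones(3, bool))
        assert kl_pssm == pytest.approx(0.0, abs=1e-7)


class TestTvRegularization:
    def test_identical_layers_zero(self, rng):
        lw = {"K": rng.standard_normal((4, 4, 3))}
        assert tv_regularization([lw, dict(lw), dict(lw)]) == 0.0

    def test_two_entry_difference(self):
        a = {"K": np.zeros((2, 2))}
        b = {"K": np.zeros((2, 2))}
        b["K"][0, 0] = 0.5
        b["K"][1, 1] = 0.5
        assert tv_regularization([a, b]) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        layers = [{"K": rng.standard_normal((3, 3, 5)),
                   "g": rng.standard_normal((3, 1))} for _ in range(4)]
        got = tv_regularization(layers)
        want = 0.0
        for a, b in zip(layers[:-1], layers[1:]):
            for key in a:
                for x, y in zip(a[key].ravel(), b[key].ravel()):
                    want += abs(x - y)
        assert got == pytest.approx(want, abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            tv_regularization([{"K": np.zeros((2, 2))}, {"K": np.zeros((3, 3))}])

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            tv_regularization([{"K": np.zeros((2, 2))}])


class TestTotalObjective:
    def test_total_is_sum_of_parts(self, small_dataset, tiny_config):
        w = init_weights(tiny_config)
        beta = 1e-4
        rep = total_objective(small_dataset[:2], w, tiny_config, beta=beta)
        parts = (rep.fold_loss + rep.design_kl_pssm + rep.design_kl_seq
                 + beta * rep.tv_reg)
        assert rep.total == pytest.approx(parts, abs=1e-8)

    def test_design_only_mode_excludes_fold(self, small_dataset, tiny_config):
        w = init_weights(tiny_config)
        rep = total_objective(small_dataset[:2], w, tiny_config,
                              direction_mode="design_only", beta=0.0)
        assert rep.fold_loss == 0.0
        assert rep.total == pytest.approx(rep.design_kl_pssm + rep.design_kl_seq,
                                          abs=1e-8)

    def test_fold_only_mode_excludes_design(self, small_dataset, tiny_config):
        w = init_weights(tiny_config)
        rep = total_objective(small_dataset[:2], w, tiny_config,
                              direction_mode="fold_only", beta=0.0)
        assert rep.design_kl_pssm == 0.0
        assert rep.total == pytest.approx(rep.fold_loss, abs=1e-8)

    def test_batch_permutation_equivariance(self, small_dataset, tiny_config):
        w = init_weights(tiny_config)
        a = total_objective(small_dataset[:3], w, tiny_config)
        b = total_objective(small_dataset[:3][::-1], w, tiny_config)
        assert a.total == pytest.approx(b.total, abs=1e-10)

    def test_unknown_mode_rejected(self, small_dataset, tiny_config):
        w = init_weights(tiny_config)
        with pytest.raises(ValueError):
            total_objective(small_dataset[:1], w, tiny_config,
                            direction_mode="sideways")
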