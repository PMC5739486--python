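import numpy as np
import pytest

from scnct.network import (
    SCNArchitecture, CompetitiveBlockParams, SCNModel, ModelDefinitionError,
    competitive_block_forward, scn_forward, scn_loss, conv2d_same,
    save_checkpoint, load_checkpoint,
)
from scnct.training import _loss_and_grads


def brute_force_block(a_prev, params, relu=True):
    """Per-pixel, per-scale loop: independent maxout oracle."""
    h, w, c_in = a_prev.shape
    c_out = params.out_channels
    per_scale = []
    for k in params.scales:
        pad = (k - 1) // 2
        xp = np.pad(a_prev, ((pad, pad), (pad, pad), (0, 0)))
        z = np.zeros((h, w, c_out))
        for i in range(h):
            for j in range(w):
                patch = xp[i:i + k, j:j + k, :]  # (k, k, C_in)
                for f in range(c_out):
                    z[i, j, f] = (
                        patch * params.weights[k][f].transpose(1, 2, 0)
                    ).sum() + params.biases[k][f]
        per_scale.append(np.maximum(z, 0.0) if relu else z)
    return np.max(np.stack(per_scale), axis=0)


def random_block(rng, scales, c_in, c_out, std=0.5):
    w = {k: rng.normal(0, std, (c_out, c_in, k, k)) for k in scales}
    b = {k: rng.normal(0, std, c_out) for k in scales}
    return CompetitiveBlockParams(w, b)


class TestCompetitiveBlock:
    @pytest.mark.parametrize("scales", [(3,), (1, 3), (1, 3, 5), (1, 3, 5, 7)])
    def test_matches_brute_force_oracle(self, rng, scales):
        params = random_block(rng, scales, c_in=2, c_out=4)
        a = rng.normal(0, 1, (8, 8, 2))
        out = competitive_block_forward(a, params)
        oracle = brute_force_block(a, params)
        assert np.max(np.abs(out - oracle)) < 1e-6

    def test_single_scale_reduces_to_relu_convolution(self, rng):
        params = random_block(rng, (3,), c_in=3, c_out=2)
        a = rng.normal(0, 1, (6, 7, 3))
        out = competitive_block_forward(a, params)
        x = np.ascontiguousarray(a.transpose(2, 0, 1))[None]
        conv = conv2d_same(x, params.weights[3], params.biases[3])[0]
        expected = np.maximum(conv, 0.0).transpose(1, 2, 0)
        assert np.allclose(out, expected, atol=1e-12)

    def test_dead_block_outputs_zero(self, rng):
        w = {k: np.zeros((4, 2, k, k)) for k in (1, 3)}
        b = {k: np.full(4, -10.0) for k in (1, 3)}
        params = CompetitiveBlockParams(w, b)
        out = competitive_block_forward(rng.normal(0, 1, (5, 5, 2)), params)
        assert np.all(out == 0.0)

    def test_output_nonnegative_and_dominates_each_scale(self, rng):
        params = random_block(rng, (1, 3, 5), c_in=2, c_out=3)
        a = rng.normal(0, 1, (9, 9, 2))
        out = competitive_block_forward(a, params)
        assert np.all(out >= 0.0)
        for k in params.scales:
            single = CompetitiveBlockParams(
                {k: params.weights[k]}, {k: params.biases[k]})
            assert np.all(out >= competitive_block_forward(a, single) - 1e-12)

    def test_adding_scale_never_decreases_output(self, rng):
        base = random_block(rng, (1, 3), c_in=2, c_out=3)
        extra_w = dict(base.weights)
        extra_b = dict(base.biases)
        extra_w[5] = rng.normal(0, 0.5, (3, 2, 5, 5))
        extra_b[5] = rng.normal(0, 0.5, 3)
        bigger = CompetitiveBlockParams(extra_w, extra_b)
        a = rng.normal(0, 1, (8, 8, 2))
        assert np.all(
            competitive_block_forward(a, bigger)
            >= competitive_block_forward(a, base) - 1e-12)

    def test_channel_mismatch_raises(self, rng):
        params = random_block(rng, (3,), c_in=2, c_out=2)
        with pytest.raises(ModelDefinitionError, match="channels"):
            competitive_block_forward(rng.normal(0, 1, (5, 5, 3)), params)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ModelDefinitionError):
            CompetitiveBlockParams(
                {2: rng.normal(0, 1, (1, 1, 2, 2))}, {2: np.zeros(1)})


class TestSCNForward:
    def test_identity_network_passes_image_through(self):
        arch = SCNArchitecture(depth=1, scales=(1,), filters=1,
                               final_relu=False)
        w = {1: np.ones((1, 1, 1, 1))}
        b = {1: np.zeros(1)}
        model = SCNModel(arch, [CompetitiveBlockParams(w, b)])
        img = np.random.default_rng(0).uniform(0, 1, (12, 12))
        assert np.allclose(scn_forward(img, model), img, atol=1e-12)

    def test_fully_convolutional_consistency(self, rng):
        """A 64x64 crop processed alone equals the matching crop of the
        full-image output away from the receptive-field border."""
        arch = SCNArchitecture(depth=3, scales=(1, 3, 5), filters=4)
        model = SCNModel.initialize(arch, rng, 0.5)
        full = rng.uniform(0, 1, (96, 96))
        r0, c0 = 16, 24
        patch = full[r0:r0 + 64, c0:c0 + 64]
        out_full = scn_forward(full, model)
        out_patch = scn_forward(patch, model)
        margin = (5 - 1) // 2 * 3  # (max kernel - 1)/2 * depth
        inner = slice(margin, 64 - margin)
        assert np.allclose(
            out_patch[inner, inner],
            out_full[r0 + margin:r0 + 64 - margin,
                     c0 + margin:c0 + 64 - margin],
            atol=1e-9,
        )

    def test_parameter_count_closed_form(self):
        arch = SCNArchitecture(depth=5, scales=(1, 3, 5), filters=96)
        model = SCNModel.initialize(arch, np.random.default_rng(0), 0.01)
        # sum over blocks/scales of (C_in * k^2 + 1) * C_out
        expected = 0
        c_in = 1
        for i in range(5):
            c_out = 1 if i == 4 else 96
            expected += sum((c_in * k * k + 1) * c_out for k in (1, 3, 5))
            c_in = c_out
        assert arch.n_parameters() == expected
        assert model.n_parameters() == expected

    def test_translation_equivariance_interior(self, rng):
        arch = SCNArchitecture(depth=2, scales=(1, 3), filters=3)
        model = SCNModel.initialize(arch, rng, 0.5)
        img = rng.uniform(0, 1, (40, 40))
        shifted = np.roll(img, (3, 5), axis=(0, 1))
        out = scn_forward(img, model)
        out_shifted = scn_forward(shifted, model)
        m = 10  # stay away from wrap-around and padding borders
        assert np.allclose(
            np.roll(out, (3, 5), axis=(0, 1))[m:-m, m:-m],
            out_shifted[m:-m, m:-m], atol=1e-9)

    def test_mismatched_blocks_rejected(self, rng):
        arch = SCNArchitecture(depth=2, scales=(3,), filters=4)
        blocks = [random_block(rng, (3,), 1, 4),
                  random_block(rng, (3,), 3, 1)]  # wrong chain: 4 != 3
        with pytest.raises(ModelDefinitionError, match="chain"):
            SCNModel(arch, blocks)


class TestLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        arch = SCNArchitecture(depth=1, scales=(1,), filters=1)
        model = SCNModel.initialize(arch, rng, 0.01)
        x = rng.uniform(0, 1, (4, 4))
        assert scn_loss(x, x, model, alpha=0.0) == 0.0

    def test_pure_decay_term(self, rng):
        arch = SCNArchitecture(depth=2, scales=(1, 3), filters=2)
        model = SCNModel.initialize(arch, rng, 0.3)
        x = rng.uniform(0, 1, (4, 4))
        total_sq = sum(
            float((w**2).sum())
            for blk in model.blocks for w in blk.weights.values())
        assert scn_loss(x, x, model, alpha=0.5) == pytest.approx(
            0.5 * total_sq, rel=1e-12)

    def test_hand_enumerated_2x2(self, rng):
        arch = SCNArchitecture(depth=1, scales=(1,), filters=1)
        model = SCNModel.initialize(arch, rng, 0.1)
        pred = np.array([[0.2, 0.4], [0.6, 0.8]])
        target = np.array([[0.1, 0.5], [0.5, 1.0]])
        hand = 0.01 + 0.01 + 0.01 + 0.04  # sum of squared differences
        w_sq = float(model.blocks[0].weights[1][0, 0, 0, 0] ** 2)
        assert scn_loss(pred, target, model, alpha=2.0) == pytest.approx(
            hand + 2.0 * w_sq, rel=1e-12)

    def test_batch_reduction_sums_pixels_means_batch(self, rng):
        arch = SCNArchitecture(depth=1, scales=(1,), filters=1)
        model = SCNModel.initialize(arch, rng, 0.1)
        pred = rng.uniform(0, 1, (3, 1, 4, 4))
        target = rng.uniform(0, 1, (3, 1, 4, 4))
        per_sample = [((pred[i] - target[i]) ** 2).sum() for i in range(3)]
        assert scn_loss(pred, target, model, 0.0) == pytest.approx(
            np.mean(per_sample), rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        arch = SCNArchitecture(depth=1, scales=(1,), filters=1)
        model = SCNModel.initialize(arch, rng, 0.1)
        with pytest.raises(ValueError, match="shape"):
            scn_loss(np.zeros((3, 3)), np.zeros((4, 4)), model)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        rng = np.random.default_rng(0)
        arch = SCNArchitecture(depth=3, scales=(1, 3, 5), filters=4)
        model = SCNModel.initialize(arch, rng, 0.1)
        x = rng.normal(0.3, 0.2, (2, 1, 7, 7))
        y = rng.normal(0.3, 0.2, (2, 1, 7, 7))
        loss, grads = _loss_and_grads(model, x, y, alpha=1e-3)
        params = [a for *_n, a in model.parameters()]
        eps = 1e-6
        for pi in range(len(params)):
            p = params[pi]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            old = p[idx]
            p[idx] = old + eps
            lp, _ = _loss_and_grads(model, x, y, alpha=1e-3)
            p[idx] = old - eps
            lm, _ = _loss_and_grads(model, x, y, alpha=1e-3)
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[pi][idx]
            assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1.0)


class TestCheckpoint:
    def test_round_trip_preserves_weights(self, rng, tmp_path):
        arch = SCNArchitecture(depth=2, scales=(1, 3), filters=3)
        model = SCNModel.initialize(arch, rng, 0.1)
        path = tmp_path / "model.npz"
        save_checkpoint(path, model)
        again = load_checkpoint(path)
        assert again.arch == model.arch
        img = rng.uniform(0, 1, (16, 16))
        assert np.allclose(scn_forward(img, again), scn_forward(img, model))

    def test_descriptor_weight_mismatch_refused(self, rng, tmp_path):
        arch = SCNArchitecture(depth=2, scales=(1, 3), filters=3)
        model = SCNModel.initialize(arch, rng, 0.1)
        path = tmp_path / "model.npz"
        save_checkpoint(path, model)
        import numpy as _np
        data = dict(_np.load(path))
        data["block0_k3_W"] = data["block0_k3_W"][:, :, :1, :1]
        _np.savez(path, **data)
        with pytest.raises(ModelDefinitionError):
            load_checkpoint(path)
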