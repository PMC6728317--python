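"""Numerical core: layer gradients, optimizers, losses, schedules, models."""

import numpy as np
import pytest

from wedgenet.nn import (Adam, DualPathDiscriminator, RMSprop, RRDBGenerator,
                         TomoDiscriminator, UNetGenerator, lr_for_epoch,
                         lsgan_d_loss, mse_loss, ralsgan_d_loss,
                         ralsgan_g_loss)
from wedgenet.nn.layers import (BatchNorm2d, Conv2d, GroupNorm, LeakyReLU,
                                Linear, MaxPool2x2)
from wedgenet.train import load_checkpoint, save_checkpoint


def _numgrad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestLayerGradients:
    """Central-difference checks of the hand-written backward passes."""

    def _check(self, layer, x, train=True, tol=2e-2):
        rng = np.random.default_rng(0)
        t = rng.normal(size=layer.forward(x, train)[0].shape).astype(np.float32)

        def loss():
            y, _ = layer.forward(x, train)
            return float(((y - t) ** 2).sum())

        y, cache = layer.forward(x, train)
        dx = layer.backward((2 * (y - t)).astype(np.float32), cache)
        gx = _numgrad(loss, x)
        assert np.abs(dx - gx).max() / max(np.abs(gx).max(), 1e-8) < tol
        return loss

    def test_conv_input_grad(self):
        rng = np.random.default_rng(1)
        conv = Conv2d(2, 3, 3, stride=2, dilation=2, rng=rng)
        x = rng.normal(size=(2, 2, 9, 8)).astype(np.float32)
        self._check(conv, x)

    def test_conv_weight_grad(self):
        rng = np.random.default_rng(6)
        conv = Conv2d(2, 3, 3, stride=2, dilation=2, rng=rng)
        x = rng.normal(size=(2, 2, 9, 8)).astype(np.float32)

        def loss():
            y, _ = conv.forward(x)
            return float((y ** 2).sum())

        y, cache = conv.forward(x)
        conv.weight.zero_grad()
        conv.backward(2 * y, cache)
        gw = _numgrad(loss, conv.weight.data)
        assert np.abs(conv.weight.grad - gw).max() / np.abs(gw).max() < 2e-2

    def test_groupnorm_grad(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
        self._check(GroupNorm(4, 2), x)

    def test_batchnorm_grad(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        self._check(BatchNorm2d(3, momentum=0.0), x)

    def test_maxpool_grad_routes_to_argmax(self):
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        pool = MaxPool2x2()
        y, cache = pool.forward(x)
        dy = np.ones_like(y)
        dx = pool.backward(dy, cache)
        np.testing.assert_array_equal(
            dx[0, 0], [[0, 0, 0, 0], [0, 1, 0, 1], [0, 0, 0, 0], [0, 1, 0, 1]])

    def test_linear_grad(self):
        rng = np.random.default_rng(4)
        lin = Linear(5, 3, rng=rng)
        x = rng.normal(size=(4, 5)).astype(np.float32)
        self._check(lin, x)


class TestOptimizers:
    def test_adam_minimizes_quadratic(self):
        from wedgenet.nn.layers import Parameter
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1, weight_decay=0.0)
        for _ in range(200):
            p.zero_grad()
            p.grad[...] = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_rmsprop_minimizes_quadratic(self):
        from wedgenet.nn.layers import Parameter
        p = Parameter(np.array([5.0, -3.0]))
        opt = RMSprop([p], lr=0.05, weight_decay=0.0)
        for _ in range(300):
            p.zero_grad()
            p.grad[...] = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-1


class TestSchedule:
    def test_warmup_plateau_and_decays(self):
        # 1e-4, 2e-4, 4e-4 warmup; tenfold decays entering epochs 20 and 28
        assert lr_for_epoch(1) == pytest.approx(1e-4)
        assert lr_for_epoch(2) == pytest.approx(2e-4)
        assert lr_for_epoch(3) == pytest.approx(4e-4)
        for e in range(4, 20):
            assert lr_for_epoch(e) == pytest.approx(4e-4)
        for e in range(20, 28):
            assert lr_for_epoch(e) == pytest.approx(4e-5)
        for e in range(28, 31):
            assert lr_for_epoch(e) == pytest.approx(4e-6)

    def test_one_based(self):
        with pytest.raises(ValueError):
            lr_for_epoch(0)


class TestLosses:
    def test_mse_zero_for_identical(self):
        x = np.random.default_rng(0).random((2, 4, 4)).astype(np.float32)
        loss, grad = mse_loss(x, x)
        assert loss == 0.0 and not grad.any()

    def test_ralsgan_matches_hand_oracle(self):
        # independent arithmetic oracle, written as explicit loops
        sr, sf = [1.0, 0.0], [0.0, 0.0]
        mr = sum(sr) / 2
        mf = sum(sf) / 2
        d_oracle = 0.5 * (sum((r - mf - 1) ** 2 for r in sr) / 2
                          + sum((f - mr + 1) ** 2 for f in sf) / 2)
        g_oracle = 0.5 * (sum((r - mf + 1) ** 2 for r in sr) / 2
                          + sum((f - mr - 1) ** 2 for f in sf) / 2)
        d_loss, _, _ = ralsgan_d_loss(sr, sf)
        g_loss, _, _ = ralsgan_g_loss(sr, sf)
        assert d_loss == pytest.approx(d_oracle, abs=1e-9)
        assert g_loss == pytest.approx(g_oracle, abs=1e-9)

    def test_ralsgan_gradients_numerically(self):
        rng = np.random.default_rng(5)
        sr = rng.normal(size=4)
        sf = rng.normal(size=4)
        _, dsr, dsf = ralsgan_d_loss(sr, sf)
        eps = 1e-6
        for i in range(4):
            up, dn = sr.copy(), sr.copy()
            up[i] += eps
            dn[i] -= eps
            num = (ralsgan_d_loss(up, sf)[0] - ralsgan_d_loss(dn, sf)[0]) / (2 * eps)
            assert num == pytest.approx(dsr[i], abs=1e-6)

    def test_relativistic_needs_two_samples(self):
        with pytest.raises(ValueError):
            ralsgan_d_loss([1.0], [0.0, 1.0])

    def test_lsgan_switch(self):
        d, _, _ = lsgan_d_loss([1.0, 1.0], [0.0, 0.0])
        assert d == pytest.approx(0.0)


class TestModels:
    def test_generator_shape_contract(self):
        g = RRDBGenerator(n_blocks=1, feature_depth=8, growth_channels=4, seed=0)
        x = np.random.default_rng(0).random((2, 1, 30, 32), dtype=np.float32)
        y = g.predict(x)
        assert y.shape == x.shape

    def test_param_count_deterministic_and_monotone(self):
        cfg = dict(feature_depth=8, growth_channels=4)
        a = RRDBGenerator(n_blocks=2, seed=0, **cfg).n_parameters()
        b = RRDBGenerator(n_blocks=2, seed=5, **cfg).n_parameters()
        c = RRDBGenerator(n_blocks=4, seed=0, **cfg).n_parameters()
        assert a == b
        assert c > a

    def test_discriminator_scalar_score_and_conditioning(self):
        d = DualPathDiscriminator(feature_depth=8, slow_path_depth=3,
                                  fast_path_depth=2, seed=0)
        rng = np.random.default_rng(1)
        cand = rng.random((3, 1, 30, 32), dtype=np.float32)
        cond_a = rng.random((3, 1, 30, 32), dtype=np.float32)
        cond_b = rng.random((3, 1, 30, 32), dtype=np.float32)
        sa, _ = d.forward(np.concatenate([cand, cond_a], axis=1), train=False)
        sb, _ = d.forward(np.concatenate([cand, cond_b], axis=1), train=False)
        assert sa.shape == (3,)
        assert np.abs(sa - sb).max() > 1e-7  # CGAN wiring is live

    def test_groups_must_divide_depth(self):
        with pytest.raises(ValueError):
            DualPathDiscriminator(feature_depth=10, group_norm_groups=4)

    def test_slow_path_deeper_than_fast(self):
        with pytest.raises(ValueError):
            DualPathDiscriminator(slow_path_depth=2, fast_path_depth=3)

    def test_unet_shape_and_inference_determinism(self):
        u = UNetGenerator(depth=2, base_channels=4, seed=0)
        x = np.random.default_rng(2).random((1, 1, 32, 32), dtype=np.float32)
        a = u.predict(x)
        b = u.predict(x)
        assert a.shape == x.shape
        np.testing.assert_array_equal(a, b)

    def test_unet_trained_skip_liveness(self):
        # after brief training on a denoising task the top skip carries more
        # signal than the bottleneck
        rng = np.random.default_rng(0)
        u = UNetGenerator(depth=2, base_channels=8, norm=False, seed=0)
        opt = Adam(u.parameters(), lr=2e-3, weight_decay=0.0)
        clean = rng.random((16, 1, 32, 32), dtype=np.float32)
        noisy = clean + rng.normal(0, 0.3, clean.shape).astype(np.float32)
        for _ in range(60):
            y, c = u.forward(noisy)
            _, dg = mse_loss(y, clean)
            opt.zero_grad()
            u.backward(dg, c)
            opt.step()
        x = noisy[:1]
        base = u.forward(x, train=False)[0]
        no_bot = u.forward(x, train=False, ablate="bottleneck")[0]
        no_skip = u.forward(x, train=False, ablate="top_skip")[0]
        assert np.abs(base - no_bot).mean() < np.abs(base - no_skip).mean()

    def test_tomo_discriminator_scalar(self):
        d = TomoDiscriminator(feature_depth=8, n_layers=2, seed=0)
        x = np.random.default_rng(3).random((2, 2, 32, 32), dtype=np.float32)
        s, _ = d.forward(x, train=False)
        assert s.shape == (2,)

    def test_checkpoint_roundtrip(self, tmp_path):
        g = RRDBGenerator(n_blocks=1, feature_depth=8, growth_channels=4, seed=3)
        p = tmp_path / "g.npz"
        save_checkpoint(g, p)
        h = load_checkpoint(p)
        x = np.random.default_rng(4).random((1, 1, 12, 16), dtype=np.float32)
        np.testing.assert_array_equal(g.predict(x), h.predict(x))
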