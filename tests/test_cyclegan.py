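"""Network construction, losses, gradients, replay buffer, training mechanics."""

import numpy as np
import pytest

from bonesup import nn
from bonesup.cyclegan import (
    GanConfig,
    ReplayBuffer,
    TrainedModel,
    compute_losses,
    from_unit,
    init_models,
    load_model,
    save_model,
    suppress_bone,
    to_unit,
    train,
)
from bonesup.errors import ConfigurationError, SizeError
from bonesup.projection import ProjectionImage

TINY = GanConfig(image_size=16, base_channels=4, n_res_blocks=1, batch_size=2,
                 n_epochs=1, seed=0)


def numerical_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestLayerGradients:
    """Analytic backward passes agree with central differences."""

    @pytest.mark.parametrize("layer_fn,shape", [
        (lambda r: nn.Conv2d(2, 3, 3, stride=1, pad=1, rng=r, w_sd=0.3), (2, 2, 5, 5)),
        (lambda r: nn.Conv2d(2, 2, 4, stride=2, pad=1, rng=r, w_sd=0.3), (1, 2, 6, 6)),
        (lambda r: nn.InstanceNorm2d(2), (2, 2, 4, 4)),
        (lambda r: nn.Tanh(), (1, 2, 3, 3)),
        (lambda r: nn.LeakyReLU(0.2), (1, 2, 3, 3)),
        (lambda r: nn.UpsampleNearest2x(), (1, 2, 3, 3)),
        (lambda r: nn.ResBlock(2, r), (1, 2, 4, 4)),
    ])
    def test_input_gradient(self, layer_fn, shape, rng):
        layer = layer_fn(rng)
        x = rng.normal(0, 1, shape).astype(np.float32)
        y0, _ = layer.forward(x)
        w = rng.normal(0, 1, y0.shape).astype(np.float32)  # fixed projection vector

        def loss():
            y, _ = layer.forward(x)
            return float((y.astype(np.float64) * w).sum())

        y, ctx = layer.forward(x)
        dx = layer.backward(w, ctx, accumulate=True)
        num = numerical_grad(loss, x)
        np.testing.assert_allclose(dx, num, rtol=2e-2, atol=2e-2)

    def test_conv_weight_gradient(self, rng):
        conv = nn.Conv2d(2, 2, 3, pad=1, rng=rng, w_sd=0.3)
        x = rng.normal(0, 1, (1, 2, 5, 5)).astype(np.float32)
        w = rng.normal(0, 1, (1, 2, 5, 5)).astype(np.float32)

        def loss():
            y, _ = conv.forward(x)
            return float((y.astype(np.float64) * w).sum())

        _, ctx = conv.forward(x)
        conv.W.grad[...] = 0
        conv.backward(w, ctx, accumulate=True)
        num = numerical_grad(loss, conv.W.value)
        np.testing.assert_allclose(conv.W.grad, num, rtol=2e-2, atol=2e-2)


class TestModelConstruction:
    def test_init_deterministic(self):
        a, b = init_models(TINY), init_models(TINY)
        for pa, pb in zip(a.G_XY.params(), b.G_XY.params()):
            assert np.array_equal(pa.value, pb.value)
        for pa, pb in zip(a.D_X.params(), b.D_X.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_generator_preserves_shape(self, rng):
        m = init_models(TINY)
        x = rng.normal(0, 0.5, (2, 1, 16, 16)).astype(np.float32)
        y, _ = m.G_XY.forward(x)
        assert y.shape == x.shape
        assert np.all(np.abs(y) <= 1.0)  # tanh range closure

    def test_patchgan_map_shape(self, rng):
        # three stride-2 layers: 64 -> 8x8 single-channel patch map
        cfg = GanConfig(image_size=64, base_channels=4, n_res_blocks=1, seed=0)
        m = init_models(cfg)
        d, _ = m.D_X.forward(rng.normal(0, 1, (1, 1, 64, 64)).astype(np.float32))
        assert d.shape == (1, 1, 8, 8)

    def test_image_size_not_divisible_rejected(self):
        with pytest.raises(ConfigurationError):
            GanConfig(image_size=30)


class TestLosses:
    def test_identity_generators_zero_cycle(self, rng):
        m = init_models(TINY)

        class Identity:
            def forward(self, x):
                return x, None

        m.G_XY = Identity()
        m.G_YX = Identity()
        x = rng.uniform(-1, 1, (2, 1, 16, 16)).astype(np.float32)
        y = rng.uniform(-1, 1, (2, 1, 16, 16)).astype(np.float32)
        losses = compute_losses(x, y, m, TINY)
        assert losses["cycle"] == 0.0
        assert losses["identity"] == 0.0

    def test_half_output_discriminator_quarter_loss(self, rng):
        m = init_models(TINY)

        class Half:
            def forward(self, x):
                return np.full((x.shape[0], 1, 2, 2), 0.5, dtype=np.float32), None

        m.D_X = Half()
        m.D_Y = Half()
        x = rng.uniform(-1, 1, (1, 1, 16, 16)).astype(np.float32)
        losses = compute_losses(x, x.copy(), m, TINY)
        # least-squares loss is 0.25 per patch for real and fake alike
        assert losses["adv_D_X"] == pytest.approx(0.25)
        assert losses["adv_D_Y"] == pytest.approx(0.25)
        assert losses["adv_G"] == pytest.approx(0.5)  # two 0.25 streams vs target 1

    def test_cycle_loss_linear_in_lambda(self, rng):
        x = rng.uniform(-1, 1, (1, 1, 16, 16)).astype(np.float32)
        y = rng.uniform(-1, 1, (1, 1, 16, 16)).astype(np.float32)
        m = init_models(TINY)
        l1 = compute_losses(x, y, m, TINY)
        import dataclasses

        l2 = compute_losses(x, y, m, dataclasses.replace(TINY, lambda_cycle=20.0))
        assert l2["cycle"] == pytest.approx(2.0 * l1["cycle"], rel=1e-6)


class TestReplayBuffer:
    def test_returns_batch_sized_output_and_stated_swap_rule(self, rng):
        buf = ReplayBuffer(4, rng)
        first = rng.normal(0, 1, (4, 1, 2, 2)).astype(np.float32)
        out = buf.query(first)
        assert out.shape == first.shape
        np.testing.assert_array_equal(out, first)  # pool filling returns inputs
        assert len(buf.images) == 4
        swapped_in = 0
        for _ in range(50):
            batch = rng.normal(0, 1, (2, 1, 2, 2)).astype(np.float32)
            out = buf.query(batch)
            assert out.shape == batch.shape
            assert len(buf.images) == 4  # never grows past capacity
            for b, o in zip(batch, out):
                if not np.array_equal(b, o):
                    swapped_in += 1
        assert 20 <= swapped_in <= 80  # ~50% swap rule over 100 queries


class TestTrainingMechanics:
    def _toy_domains(self, rng, n=12, size=16):
        xs = rng.integers(40, 216, size=(n, size, size)).astype(np.uint8)
        return xs, xs.copy()

    def test_fixed_seed_identical_histories(self, rng):
        X, Y = self._toy_domains(rng)
        cfg = GanConfig(image_size=16, base_channels=4, n_res_blocks=1, batch_size=2,
                        n_epochs=2, seed=3)
        h1 = train((X, Y), cfg).history
        h2 = train((X, Y), cfg).history
        assert h1 == h2

    def test_identity_task_reduces_reconstruction_error(self, rng):
        # X and Y hold the same images: G_XY should move toward identity
        xs = np.stack([
            np.clip(
                128 + 80 * np.sin(np.linspace(0, 3 + i, 16))[:, None]
                * np.cos(np.linspace(0, 2 + i, 16))[None, :]
                + rng.normal(0, 8, (16, 16)),
                0, 255,
            ).astype(np.uint8)
            for i in range(12)
        ])
        cfg = GanConfig(image_size=16, base_channels=4, n_res_blocks=1, batch_size=2,
                        n_epochs=40, max_updates=200, seed=1, residual_generator=False)
        model0 = init_models(cfg)
        x = to_unit(xs)
        y0, _ = model0.G_XY.forward(x)
        err0 = float(np.mean(np.abs(y0 - x)))
        model = train((xs, xs.copy()), cfg)
        y1, _ = model.G_XY.forward(x)
        err1 = float(np.mean(np.abs(y1 - x)))
        assert err1 < err0

    def test_single_step_descends_generator_objective(self, rng):
        # gradient sanity: one small-lr Adam step on a fixed batch lowers
        # that batch's generator loss (adv + cycle)
        X, Y = self._toy_domains(rng, n=4)
        cfg = GanConfig(image_size=16, base_channels=4, n_res_blocks=1, batch_size=4,
                        n_epochs=1, max_updates=1, seed=2, learning_rate=1e-5,
                        residual_generator=False)
        m0 = init_models(cfg)
        x, y = to_unit(X), to_unit(Y)
        before = compute_losses(x, y, m0, cfg)
        m1 = train((X, Y), cfg)  # exactly one update (D also steps, on the buffer)
        after = compute_losses(x, y, m1, cfg)
        obj_before = before["adv_G"] + before["cycle"]
        obj_after = after["adv_G"] + after["cycle"]
        assert obj_after < obj_before

    def test_value_range_roundtrip_identity(self, rng):
        pix = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        back = from_unit(to_unit(pix[None])[0, 0])
        assert np.max(np.abs(back.astype(int) - pix.astype(int))) <= 1

    def test_empty_domain_rejected(self):
        with pytest.raises(ConfigurationError):
            train((np.zeros((0, 16, 16), np.uint8), np.zeros((2, 16, 16), np.uint8)), TINY)


@pytest.fixture(scope="module")
def tiny_model():
    return init_models(TINY)


class TestSuppressAndCheckpoint:

    def test_same_input_same_output(self, tiny_model, rng):
        img = ProjectionImage(pixels=rng.integers(0, 256, (16, 16)).astype(np.uint8),
                              value_domain="8bit", angle_deg=45.0, domain_tag="with_bone")
        a = suppress_bone(tiny_model, img)
        b = suppress_bone(tiny_model, img)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.domain_tag == "suppressed"

    def test_large_image_tilewise_shape(self, tiny_model, rng):
        img = ProjectionImage(pixels=rng.integers(0, 256, (48, 48)).astype(np.uint8),
                              value_domain="8bit", angle_deg=45.0, domain_tag="with_bone")
        out = suppress_bone(tiny_model, img)
        assert out.pixels.shape == (48, 48)
        assert out.pixels.dtype == np.uint8

    def test_too_small_rejected(self, tiny_model):
        img = ProjectionImage(pixels=np.zeros((2, 2), np.uint8), value_domain="8bit",
                              angle_deg=0.0, domain_tag="with_bone")
        with pytest.raises(SizeError):
            suppress_bone(tiny_model, img)

    def test_checkpoint_roundtrip(self, tiny_model, tmp_path, rng):
        save_model(tiny_model, tmp_path / "ck")
        loaded = load_model(tmp_path / "ck")
        x = rng.normal(0, 0.5, (1, 1, 16, 16)).astype(np.float32)
        ya, _ = tiny_model.G_XY.forward(x)
        yb, _ = loaded.G_XY.forward(x)
        assert np.array_equal(ya, yb)
        assert loaded.config == tiny_model.config
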