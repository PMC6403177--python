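"""Architecture pinning, layer mechanics, initialization, training."""

import numpy as np
import pytest

from vesselseg.nn import (
    PRESETS,
    UNet2D,
    UNetConfig,
    count_parameters,
    preset_config,
    train,
)
from vesselseg.nn.layers import (
    Conv2d,
    MaxPool2x2,
    Upsample2x,
    glorot_uniform_limit,
)
from vesselseg.nn.loss import soft_dice
from vesselseg.sampling import PatchPair


def test_published_parameter_totals():
    assert count_parameters(UNetConfig(base_width=64)) == 31_377_793
    assert count_parameters(UNetConfig(base_width=32)) == 7_846_081


def test_learned_upconv_variant_differs():
    # The decoder must up-sample without parameters; the learned 2x2
    # up-convolution alternative lands on a different total.
    assert count_parameters(UNetConfig(base_width=64), upsampling="transpose") == 31_030_593


def test_per_layer_counting_formula():
    cfg = UNetConfig(base_width=64)
    # first encoder conv 1->64: 9*1*64 + 64
    assert 9 * 1 * 64 + 64 == 640
    model = UNet2D(UNetConfig(base_width=8, depth=2, patch_size=16))
    first = model.encoder[0].conv1
    assert first.n_params == 9 * 1 * 8 + 8


@pytest.mark.parametrize("base_width", [8, 16, 32])
@pytest.mark.parametrize("depth", [2, 3, 4])
def test_built_model_matches_closed_form(base_width, depth):
    cfg = UNetConfig(base_width=base_width, depth=depth, patch_size=2**depth * 2)
    assert UNet2D(cfg).num_parameters() == count_parameters(cfg)


def test_full_width_built_model_matches_closed_form():
    cfg = UNetConfig(base_width=64, depth=4, patch_size=96)
    assert UNet2D(cfg).num_parameters() == 31_377_793


def test_output_shape_and_range():
    model = UNet2D(UNetConfig(base_width=4, depth=2, patch_size=16, seed=1))
    x = np.random.default_rng(0).normal(size=(3, 1, 16, 16))
    out = model.forward(x)
    assert out.shape == (3, 1, 16, 16)
    assert np.all(out > 0) and np.all(out < 1)


def test_patch_size_must_match_depth():
    with pytest.raises(ValueError):
        UNetConfig(base_width=8, depth=4, patch_size=24).validate()


def test_glorot_init_bounds():
    rng = np.random.default_rng(0)
    conv = Conv2d(4, 8, 3, rng)
    limit = glorot_uniform_limit(4 * 9, 8 * 9)
    w = conv.params["w"]
    assert np.all(np.abs(w) <= limit)
    # draws should fill a good part of the admissible range
    assert w.max() > 0.8 * limit and w.min() < -0.8 * limit
    assert np.all(conv.params["b"] == 0)


def test_maxpool_and_upsample_are_adjoint_shapes(rng):
    x = rng.normal(size=(2, 3, 8, 8))
    pool = MaxPool2x2()
    up = Upsample2x()
    pooled = pool.forward(x, train=True)
    assert pooled.shape == (2, 3, 4, 4)
    assert up.forward(pooled).shape == (2, 3, 8, 8)
    # upsample backward sums each 2x2 block
    dout = rng.normal(size=(2, 3, 8, 8))
    back = up.backward(dout)
    assert np.allclose(back[0, 0, 0, 0], dout[0, 0, :2, :2].sum())


def test_model_gradients_match_finite_differences(rng):
    model = UNet2D(UNetConfig(base_width=2, depth=2, patch_size=8, seed=3))
    model.to_dtype(np.float64)
    x = rng.normal(size=(2, 1, 8, 8))
    g = (rng.random((2, 1, 8, 8)) < 0.2).astype(float)
    from vesselseg.nn.loss import soft_dice_loss_gradient

    probs = model.forward(x, train=True)
    _, dprob = soft_dice_loss_gradient(probs, g)
    model.backward(dprob)
    h = 1e-6
    for name, params, grads in model.parameters()[::3]:
        w = params["w"]
        i = tuple(rng.integers(0, s) for s in w.shape)
        orig = w[i]
        w[i] = orig + h
        lp = 1.0 - soft_dice(model.forward(x), g)
        w[i] = orig - h
        lm = 1.0 - soft_dice(model.forward(x), g)
        w[i] = orig
        fd = (lp - lm) / (2 * h)
        assert grads["w"][i] == pytest.approx(fd, rel=1e-4, abs=1e-9)


def test_checkpoint_round_trip(tmp_path, rng):
    model = UNet2D(UNetConfig(base_width=4, depth=2, patch_size=16, seed=2))
    x = rng.normal(size=(1, 1, 16, 16))
    before = model.forward(x)
    path = tmp_path / "model.npz"
    model.save(path)
    restored = UNet2D.load(path)
    assert np.array_equal(restored.forward(x), before)


def test_table_presets():
    assert PRESETS[("unet", "dice")] == dict(
        base_width=64, learning_rate=1e-4, batch_size=16, dropout_rate=0.0
    )
    cfg = preset_config("half_unet", "dice", patch_size=96)
    assert (cfg.base_width, cfg.learning_rate, cfg.batch_size, cfg.dropout_rate) == (
        32,
        1e-4,
        64,
        0.1,
    )
    with pytest.raises(KeyError):
        preset_config("unet", "nope")


def _phantom_patches(n, patch_size, seed):
    from vesselseg.phantom import PhantomConfig, generate_phantom
    from vesselseg.sampling import SamplerConfig, sample_patches

    volume, mask, label = generate_phantom(PhantomConfig(seed=seed))
    cfg = SamplerConfig(
        patch_size=patch_size,
        n_vessel_per_subject=n // 2,
        n_background_per_subject=n - n // 2,
        seed=seed,
    )
    return sample_patches(volume, label, mask, cfg)


def test_overfit_small_patch_set():
    patches = _phantom_patches(10, 16, seed=5)
    cfg = UNetConfig(base_width=4, depth=2, patch_size=16, learning_rate=1e-3,
                     batch_size=10, epochs=200, seed=0)
    model = UNet2D(cfg)
    history = train(model, patches, cfg)
    assert history.train_dice[-1] > 0.95


def test_smoke_training_loss_decreases():
    patches = _phantom_patches(200, 16, seed=6)
    cfg = UNetConfig(base_width=4, depth=2, patch_size=16, learning_rate=1e-3,
                     batch_size=16, epochs=3, seed=0)
    model = UNet2D(cfg)
    history = train(model, patches, cfg)
    assert history.loss[2] < history.loss[0]


def test_training_reproducible_bitwise():
    patches = _phantom_patches(40, 16, seed=7)
    cfg = UNetConfig(base_width=4, depth=2, patch_size=16, learning_rate=1e-3,
                     batch_size=8, epochs=2, seed=11, dropout_rate=0.1)
    states = []
    for _ in range(2):
        model = UNet2D(cfg)
        train(model, patches, cfg)
        states.append(model.state_copy())
    for key in states[0]:
        assert np.array_equal(states[0][key], states[1][key])


def test_empty_patch_set_raises():
    model = UNet2D(UNetConfig(base_width=4, depth=2, patch_size=16))
    with pytest.raises(ValueError):
        train(model, [], model.config)
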