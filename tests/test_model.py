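"""Architecture contracts: shapes, masks, codec identities, checkpoints."""

import numpy as np
import pytest

from neosep.audio import AudioSignal
from neosep.model import (ModelConfig, Separator, count_parameters,
                          frame_count, load_checkpoint, save_checkpoint)
from neosep.tensor import Tensor

TINY = ModelConfig(feature_size=32, mask_feature_size=16, conv_layers=1,
                   transformer_layers=1, num_heads=2, encoder_kernel=64)


@pytest.fixture(scope="module")
def tiny_model():
    return Separator(TINY, seed=0)


def test_frame_count_closed_form():
    # M = floor((T - kernel)/stride) + 1 for the learned codec
    assert frame_count(32_000, ModelConfig()) == 124
    assert frame_count(512, ModelConfig()) == 1


def test_encoder_output_shape_and_feature_dimension(tiny_model, rng):
    x = Tensor(rng.standard_normal((2, 1000)))
    feats = tiny_model.encode(x)
    M = (1000 - 64) // 32 + 1
    assert feats.shape == (2, 32, M)
    assert np.all(feats.data >= 0.0)       # ReLU token representation


def test_encoder_rejects_input_shorter_than_kernel(tiny_model, rng):
    with pytest.raises(ValueError):
        tiny_model.encode(Tensor(rng.standard_normal((1, 63))))


def test_masks_are_bounded_and_correctly_shaped(tiny_model, rng):
    feats = tiny_model.encode(Tensor(rng.standard_normal((2, 1000))))
    masks = tiny_model.generate_masks(feats)
    assert masks.shape == (2, 2, 32, feats.shape[-1])
    assert masks.data.min() >= 0.0 and masks.data.max() <= 1.0


def test_zero_features_give_finite_masks(tiny_model):
    feats = Tensor(np.zeros((1, 32, 10)))
    masks = tiny_model.generate_masks(feats)
    assert np.all(np.isfinite(masks.data))


def test_apply_masks_identities(tiny_model, rng):
    feats = Tensor(rng.standard_normal((1, 32, 10)))
    ones = Tensor(np.ones((1, 2, 32, 10)))
    out = Separator.apply_masks(feats, ones)
    assert np.allclose(out[0].data, feats.data)
    m = rng.uniform(0, 1, (1, 1, 32, 10))
    comp = Tensor(np.concatenate([m, 1 - m], axis=1))
    a, b = Separator.apply_masks(feats, comp)
    assert np.allclose(a.data + b.data, feats.data)


def test_decode_linearity_and_length(tiny_model, rng):
    """The decoder is affine: linear in the features around its bias."""
    feats = Tensor(rng.standard_normal((1, 32, 10)))
    out = tiny_model.decode(feats, 320)
    assert out.shape == (1, 320)
    bias_response = tiny_model.decode(Tensor(np.zeros((1, 32, 10))), 320).data
    doubled = tiny_model.decode(Tensor(2 * feats.data), 320)
    assert np.allclose(doubled.data - bias_response,
                       2 * (out.data - bias_response), atol=1e-9)


@pytest.mark.parametrize("T", [512, 4000, 32_000, 40_000])
def test_separate_returns_two_signals_of_input_length(T, rng):
    cfg = ModelConfig.small()
    model = Separator(cfg, seed=0)
    out = model.forward(rng.standard_normal((1, T)))
    assert out.shape == (1, 2, T)


def test_separate_on_audiosignal_fixed_source_order(tiny_model, rng):
    sig = AudioSignal(rng.standard_normal(1000), 4000)
    est = tiny_model.separate(sig)
    assert len(est.heart) == len(est.lung) == 1000
    est2 = tiny_model.separate(sig)
    assert np.array_equal(est.heart.samples, est2.heart.samples)


def test_fixed_mask_path_is_linear_in_input(tiny_model, rng):
    """With the mask generator bypassed and biases subtracted, the
    encoder/decoder pair is a linear map of the input."""
    x = rng.standard_normal((1, 1000))
    mask = Tensor(np.ones((1, 32, (1000 - 64) // 32 + 1)))

    def fixed_forward(inp):
        feats = tiny_model.encoder(Tensor(inp).reshape(1, 1, 1000))
        return tiny_model.decode(mask * feats, 1000).data

    zero_response = fixed_forward(np.zeros((1, 1000)))
    y1 = fixed_forward(x) - zero_response
    y2 = fixed_forward(3.0 * x) - zero_response
    assert np.allclose(y2, 3.0 * y1, atol=1e-9)


def test_encoder_decoder_parameter_count_closed_form():
    cfg = ModelConfig()
    model = Separator(cfg, seed=0)
    enc = model.encoder.num_parameters()
    dec = model.decoder.num_parameters()
    assert enc == 512 * 1 * 512 + 512 == 262_656
    assert dec == 512 * 1 * 512 + 1 == 262_145


def test_parameter_count_monotone_in_depth():
    base = count_parameters(TINY)
    deeper = count_parameters(
        ModelConfig(feature_size=32, mask_feature_size=16, conv_layers=1,
                    transformer_layers=2, num_heads=2, encoder_kernel=64))
    assert deeper > base


@pytest.mark.parametrize("variant", [
    dict(codec="stft"),
    dict(conv_layers=0, transformer_layers=5),
    dict(encoder_kernel=256, encoder_stride=128),
    dict(encoder_kernel=1024, encoder_stride=512),
    dict(feature_size=256),
    dict(feature_size=1024),
])
def test_ablation_variants_constructible_from_config(variant, rng):
    cfg = ModelConfig(mask_feature_size=32, conv_layers=variant.pop(
        "conv_layers", 1), transformer_layers=variant.pop(
        "transformer_layers", 1), num_heads=2, **variant)
    model = Separator(cfg, seed=0)
    out = model.forward(rng.standard_normal((1, 2048)))
    assert out.shape == (1, 2, 2048)


class TestStftCodec:
    CFG = ModelConfig(mask_feature_size=16, conv_layers=1,
                      transformer_layers=1, num_heads=2, codec="stft",
                      encoder_kernel=256, encoder_stride=128)

    def test_all_ones_mask_reconstructs_input(self, rng):
        model = Separator(self.CFG, seed=0)
        x = rng.standard_normal((1, 4000))
        re, im = model._stft_analysis(Tensor(x))
        y = model._stft_synthesis(re, im, 4000)
        rel = np.linalg.norm(y.data - x) / np.linalg.norm(x)
        assert rel < 1e-6

    def test_matches_scipy_spectrogram_magnitude(self):
        """Independent oracle: scipy's STFT of a pure tone peaks in the
        same bin as the conv-kernel analysis."""
        from scipy.signal import ShortTimeFFT, get_window
        model = Separator(self.CFG, seed=0)
        t = np.arange(4000) / 4000.0
        x = np.sin(2 * np.pi * 100.0 * t)
        re, im = model._stft_analysis(Tensor(x[None, :]))
        mag = np.sqrt(re.data[0] ** 2 + im.data[0] ** 2).mean(axis=1)
        expected_bin = round(100.0 * 256 / 4000.0)
        assert np.argmax(mag) == expected_bin
        stft = ShortTimeFFT(get_window("hann", 256), 128, fs=4000.0)
        smag = np.abs(stft.stft(x)).mean(axis=1)
        assert np.argmax(smag) == expected_bin

    def test_zero_mask_gives_silence(self, rng):
        model = Separator(self.CFG, seed=0)
        x = rng.standard_normal((1, 2000))
        re, im = model._stft_analysis(Tensor(x))
        zero = Tensor(np.zeros(re.shape))
        y = model._stft_synthesis(zero * re, zero * im, 2000)
        assert np.allclose(y.data, 0.0)

    def test_non_cola_hop_rejected(self):
        with pytest.raises(ValueError):
            Separator(ModelConfig(mask_feature_size=16, conv_layers=0,
                                  transformer_layers=1, num_heads=2,
                                  codec="stft", encoder_kernel=256,
                                  encoder_stride=100), seed=0)


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    x = rng.standard_normal((1, 500))
    before = tiny_model.forward(x).data
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path, metadata={"epoch": 3})
    model2, meta = load_checkpoint(path)
    assert meta["epoch"] == 3
    after = model2.forward(x).data
    assert np.allclose(before, after)
    with pytest.raises(FileNotFoundError):
        load_checkpoint(tmp_path / "missing.npz")
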