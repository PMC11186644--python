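"""Mask-based encoder / mask-generator / decoder separation network.

The network follows the learned-codec masking design popularised by
Conv-TasNet.  A strided 1-D convolution encodes the input waveform
``(1, T)`` into a non-negative feature map ``(F, M)`` (M frames); a
mask generator — a stack of residual convolution blocks followed by
pre-norm transformer blocks — produces one bounded mask per source,
shape ``(2, F, M)``; each mask multiplies the encoded features, and a
1-D transposed convolution decodes each masked map back to a waveform.
Source identities are fixed by output index (0 = heart, 1 = lung), so
no permutation-invariant training is needed.

An STFT codec variant replaces the learned encoder/decoder with fixed
windowed-DFT kernels (magnitude features, mixture-phase
reconstruction); it is expressed with the same convolution primitives
and is therefore trainable end-to-end too.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .audio import AudioSignal
from .synthesis import SourceSet
from .tensor import DTYPE, Tensor, concat, pad_last

NUM_SOURCES = 2  # heart, lung — fixed output order


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the final-model values: encoder kernel 512, feature
    size 512, mask feature size 256, conv kernel 3 with 6 conv layers,
    4 attention heads, 4 transformer layers.  ``encoder_stride``
    defaults to half the kernel (50% overlap).
    """

    encoder_kernel: int = 512
    feature_size: int = 512
    mask_feature_size: int = 256
    conv_kernel: int = 3
    conv_layers: int = 6
    num_heads: int = 4
    transformer_layers: int = 4
    encoder_stride: int | None = None
    ff_multiplier: int = 4
    mask_activation: str = "sigmoid"
    codec: str = "learned_conv"
    num_sources: int = NUM_SOURCES

    def __post_init__(self):
        if self.encoder_stride is None:
            object.__setattr__(self, "encoder_stride", self.encoder_kernel // 2)
        if self.encoder_stride > self.encoder_kernel:
            raise ValueError("encoder_stride must be <= encoder_kernel")
        if self.mask_feature_size % self.num_heads != 0:
            raise ValueError("mask_feature_size must be divisible by num_heads")
        if self.mask_activation not in ("sigmoid", "relu"):
            raise ValueError("mask_activation must be 'sigmoid' or 'relu'")
        if self.codec not in ("learned_conv", "stft"):
            raise ValueError("codec must be 'learned_conv' or 'stft'")
        if self.num_sources != NUM_SOURCES:
            raise ValueError("this separator is fixed at 2 sources")

    @property
    def codec_features(self) -> int:
        """Feature dimension the mask generator sees (F, or bins for STFT)."""
        if self.codec == "stft":
            return self.encoder_kernel // 2 + 1
        return self.feature_size

    @classmethod
    def small(cls) -> "ModelConfig":
        """Reduced configuration for CPU-scale experiments."""
        return cls(feature_size=128, mask_feature_size=64, conv_layers=2,
                   transformer_layers=2, num_heads=2)


def frame_count(n_samples: int, config: ModelConfig) -> int:
    """Number of frames M produced by the encoder for a T-sample input."""
    K, S = config.encoder_kernel, config.encoder_stride
    if config.codec == "stft":
        n_samples = n_samples + 2 * S  # internal reflection-free zero pad
    if n_samples < K:
        raise ValueError(f"input of {n_samples} samples shorter than "
                         f"kernel {K}")
    return (n_samples - K) // S + 1


class _StftKernels:
    """Fixed windowed-DFT analysis/synthesis kernels (periodic Hann)."""

    def __init__(self, kernel: int, stride: int):
        if kernel % 2 != 0:
            raise ValueError("stft kernel must be even")
        n = np.arange(kernel)
        w = 0.5 * (1.0 - np.cos(2 * np.pi * n / kernel))  # periodic Hann
        # COLA check: the shifted windows must tile to a constant.
        shifts = np.zeros(kernel)
        for s in range(0, kernel, stride):
            shifts += np.roll(w, s)
        if np.ptp(shifts) > 1e-9 * np.max(shifts):
            raise ValueError(
                f"window/hop pair (hann {kernel}, hop {stride}) does not "
                "satisfy the constant-overlap-add condition")
        f = np.arange(kernel // 2 + 1)[:, None]
        phase = 2 * np.pi * f * n[None, :] / kernel
        self.n_bins = kernel // 2 + 1
        self.ana_cos = Tensor((w * np.cos(phase))[:, None, :])
        self.ana_sin = Tensor((-w * np.sin(phase))[:, None, :])
        a = np.full(self.n_bins, 2.0)
        a[0] = 1.0
        a[-1] = 1.0
        self.syn_cos = Tensor((a[:, None] * np.cos(phase) / kernel)[:, None, :])
        self.syn_sin = Tensor((-a[:, None] * np.sin(phase) / kernel)[:, None, :])
        self.window = w
        self.stride = stride
        self.kernel = kernel

    def ola_inverse(self, n_frames: int) -> np.ndarray:
        """1 / (overlap-added window sum) over the padded support."""
        length = (n_frames - 1) * self.stride + self.kernel
        ola = np.zeros(length)
        for m in range(n_frames):
            ola[m * self.stride:m * self.stride + self.kernel] += self.window
        return 1.0 / np.maximum(ola, 1e-12)


class MaskGenerator(nn.Module):
    """Conv + transformer mask estimator: (B, F, M) -> (B, s, F, M)."""

    def __init__(self, config: ModelConfig, *, rng: np.random.Generator):
        F = config.codec_features
        N = config.mask_feature_size
        self.config = config
        self.in_proj = nn.Conv1d(F, N, 1, rng=rng)
        self.in_norm = nn.LayerNorm(N, axis=1, ndim=3)
        self.conv_blocks = [nn.ConvBlock(N, config.conv_kernel, rng=rng)
                            for _ in range(config.conv_layers)]
        self.transformer_blocks = [
            nn.TransformerBlock(N, config.num_heads, config.ff_multiplier,
                                rng=rng)
            for _ in range(config.transformer_layers)]
        self.out_proj = nn.Conv1d(N, config.num_sources * F, 1, rng=rng)

    def __call__(self, feats: Tensor) -> Tensor:
        B, F, M = feats.shape
        if F != self.config.codec_features:
            raise ValueError(f"feature dimension {F} does not match the "
                             f"configured {self.config.codec_features}")
        y = self.in_norm(self.in_proj(feats))
        for blk in self.conv_blocks:
            y = blk(y)
        y = y.transpose(0, 2, 1)                      # (B, M, N)
        y = y + Tensor(nn.sinusoidal_positions(M, y.shape[-1]))
        for blk in self.transformer_blocks:
            y = blk(y)
        y = y.transpose(0, 2, 1)                      # (B, N, M)
        y = self.out_proj(y)                          # (B, s*F, M)
        y = y.sigmoid() if self.config.mask_activation == "sigmoid" else y.relu()
        return y.reshape(B, self.config.num_sources, F, M)


class Separator(nn.Module):
    """Full separation network; see the module docstring."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        if config.codec == "learned_conv":
            self.encoder = nn.Conv1d(1, config.feature_size,
                                     config.encoder_kernel,
                                     stride=config.encoder_stride, rng=rng)
            self.decoder = nn.ConvTranspose1d(config.feature_size, 1,
                                              config.encoder_kernel,
                                              stride=config.encoder_stride,
                                              rng=rng)
            self._stft = None
        else:
            self._stft = _StftKernels(config.encoder_kernel,
                                      config.encoder_stride)
        self.mask_generator = MaskGenerator(config, rng=rng)

    # -- codec ----------------------------------------------------------
    def encode(self, x: Tensor) -> Tensor:
        """(B, T) waveform batch -> (B, F, M) non-negative features."""
        B, T = x.shape
        if self.config.codec == "stft":
            re, im = self._stft_analysis(x)
            return ((re * re + im * im) + 1e-24).sqrt()
        if T < self.config.encoder_kernel:
            raise ValueError(f"input of {T} samples shorter than encoder "
                             f"kernel {self.config.encoder_kernel}")
        return self.encoder(x.reshape(B, 1, T)).relu()

    def _stft_analysis(self, x: Tensor) -> tuple[Tensor, Tensor]:
        from .tensor import conv1d as _conv
        B, T = x.shape
        S = self.config.encoder_stride
        xp = pad_last(x, S, S).reshape(B, 1, T + 2 * S)
        re = _conv(xp, self._stft.ana_cos, None, stride=S)
        im = _conv(xp, self._stft.ana_sin, None, stride=S)
        return re, im

    def generate_masks(self, feats: Tensor) -> Tensor:
        """(B, F, M) features -> (B, s, F, M) masks."""
        return self.mask_generator(feats)

    @staticmethod
    def apply_masks(feats: Tensor, masks: Tensor) -> list[Tensor]:
        """Elementwise product per source: two (B, F, M) maps."""
        if masks.shape[0] != feats.shape[0] or masks.shape[2:] != feats.shape[1:]:
            raise ValueError(f"mask shape {masks.shape} does not match "
                             f"features {feats.shape}")
        return [masks[:, i] * feats for i in range(masks.shape[1])]

    def decode(self, masked: Tensor, out_length: int) -> Tensor:
        """(B, F, M) masked features -> (B, out_length) waveform."""
        if self.config.codec == "stft":
            raise RuntimeError("stft codec decodes with the mixture phase; "
                               "use forward()/separate()")
        B, F, M = masked.shape
        raw = self.decoder(masked.reshape(B, F, M))      # (B, 1, Lraw)
        raw = raw.reshape(B, raw.shape[-1])
        Lraw = raw.shape[-1]
        if abs(Lraw - out_length) > self.config.encoder_stride:
            raise ValueError(f"requested length {out_length} inconsistent "
                             f"with decoded length {Lraw}")
        if Lraw < out_length:
            raw = pad_last(raw, 0, out_length - Lraw)
        elif Lraw > out_length:
            raw = raw[:, :out_length]
        return raw

    def _stft_synthesis(self, re: Tensor, im: Tensor, out_length: int) -> Tensor:
        from .tensor import conv_transpose1d as _convT
        frames = _convT(re, self._stft.syn_cos, None, stride=self._stft.stride) \
            + _convT(im, self._stft.syn_sin, None, stride=self._stft.stride)
        B = frames.shape[0]
        Lp = frames.shape[-1]
        inv = self._stft.ola_inverse(re.shape[-1])
        y = frames.reshape(B, Lp) * Tensor(inv)
        S = self.config.encoder_stride
        return y[:, S:S + out_length]

    # -- full forward ----------------------------------------------------
    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """(B, T) mixture batch -> (B, 2, T) source estimates."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=DTYPE))
        B, T = x.shape
        if self.config.codec == "stft":
            re, im = self._stft_analysis(x)
            mag = ((re * re + im * im) + 1e-24).sqrt()
            masks = self.generate_masks(mag)
            outs = [self._stft_synthesis(masks[:, i] * re, masks[:, i] * im, T)
                    for i in range(self.config.num_sources)]
        else:
            feats = self.encode(x)
            masks = self.generate_masks(feats)
            outs = [self.decode(m, T) for m in self.apply_masks(feats, masks)]
        return concat([o.reshape(B, 1, T) for o in outs], axis=1)

    __call__ = forward

    def separate(self, signal: AudioSignal) -> SourceSet:
        """Split one mixture into (heart, lung) estimates of equal length."""
        est = self.forward(signal.samples[None, :]).data[0]
        return SourceSet(AudioSignal(est[0], signal.sample_rate_hz),
                         AudioSignal(est[1], signal.sample_rate_hz))


def count_parameters(config: ModelConfig) -> int:
    """Exact number of trainable scalars for a configuration."""
    return Separator(config, seed=0).num_parameters()


def parameter_megacount(config: ModelConfig) -> float:
    """Parameter count in millions, rounded to 2 decimals."""
    return round(count_parameters(config) / 1e6, 2)


# ----------------------------------------------------------------------
# Checkpoint format: single .npz with config + arrays + metadata
# ----------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: Separator, path, metadata: dict | None = None):
    path = Path(path)
    state = model.state_dict()
    payload = {f"param/{k}": v for k, v in state.items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    payload["__meta__"] = np.frombuffer(
        json.dumps({"version": CHECKPOINT_VERSION, **(metadata or {})}).encode(),
        dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[Separator, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such checkpoint: {path}")
    with np.load(path) as z:
        config = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    model = Separator(config, seed=0)
    model.load_state_dict(state)
    return model, meta
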