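"""Mono audio handling at the 4 kHz working rate.

Chest-sound recordings are processed as mono floating-point waveforms
with amplitudes nominally in [-1, 1].  Everything downstream (synthesis,
mixing, the separation network, metrics, vital-sign estimation) operates
on :class:`AudioSignal`.  WAV files are read and written with
``scipy.io.wavfile`` (float32 by default, 16-bit PCM for interchange);
rate conversion uses polyphase resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Working sample rate of the whole pipeline (Hz).
WORKING_RATE_HZ = 4000


@dataclass(frozen=True)
class AudioSignal:
    """A finite mono waveform with its sample rate.

    Parameters
    ----------
    samples
        1-D float array of amplitudes (dimensionless).
    sample_rate_hz
        Positive sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def power(self) -> float:
        """Mean squared amplitude."""
        return float(np.mean(self.samples ** 2))

    def replace(self, samples: np.ndarray) -> "AudioSignal":
        return AudioSignal(samples, self.sample_rate_hz)


def resample(signal: AudioSignal, target_rate_hz: int) -> AudioSignal:
    """Polyphase resampling to ``target_rate_hz`` (band-preserving)."""
    if target_rate_hz <= 0:
        raise ValueError("target rate must be positive")
    if target_rate_hz == signal.sample_rate_hz:
        return signal
    frac = Fraction(target_rate_hz, signal.sample_rate_hz).limit_denominator(10000)
    out = resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(out, target_rate_hz)


def read_audio(path, target_rate_hz: int = WORKING_RATE_HZ) -> AudioSignal:
    """Read a WAV file as a mono signal at ``target_rate_hz``.

    Multichannel files are averaged across channels; integer PCM is
    scaled to [-1, 1]; the result is resampled if the file's rate
    differs from the target.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    if np.issubdtype(data.dtype, np.integer):
        # symmetric with write_audio's pcm16 scaling
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return resample(AudioSignal(data, int(rate)), target_rate_hz)


def write_audio(signal: AudioSignal, path, encoding: str = "float32") -> None:
    """Write a signal to WAV; ``encoding`` is ``float32`` or ``pcm16``."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    if encoding == "float32":
        wavfile.write(path, signal.sample_rate_hz,
                      signal.samples.astype(np.float32))
    elif encoding == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 1.0)
        wavfile.write(path, signal.sample_rate_hz,
                      np.round(clipped * 32767.0).astype(np.int16))
    else:
        raise ValueError(f"unknown encoding {encoding!r}")


def normalize_peak(signal: AudioSignal) -> AudioSignal:
    """Scale so that max |sample| = 1; idempotent; errors on silence."""
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        raise ValueError("cannot peak-normalize an all-zero signal")
    return signal.replace(signal.samples / peak)
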