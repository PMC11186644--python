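"""Heart-rate and breathing-rate estimation from chest sounds.

Heart rate: the signal is band-passed to the neonatal heart-sound band
(50-250 Hz), reduced to a homomorphic envelope (low-pass-filtered
log-magnitude, exponentiated), and the beat period is found per second
as the strongest autocorrelation peak of the envelope inside the
neonatal range (default 90-230 bpm), over a sliding analysis window.
This is the envelope/periodicity front-end of the classic
segmentation-based estimators, without the HSMM decoding stage.

Breathing rate: the signal is band-passed to 300-450 Hz (where the
respiratory flow noise dominates), reduced to a smoothed power
envelope, and breaths are counted by peak detection over a sliding
window (default 20 s), producing a per-second breaths/min trace
limited to a configurable 15-100 range.

Seconds where no admissible periodicity or peak exists are flagged
invalid rather than filled in, and rate errors are averaged only over
seconds valid in both traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt

from .audio import AudioSignal


@dataclass(frozen=True)
class VitalsTrace:
    """One rate value per second; ``valid`` flags usable seconds."""

    times_s: np.ndarray      # integer seconds
    values: np.ndarray       # bpm or breaths/min
    valid: np.ndarray        # boolean
    kind: str                # "heart" or "breathing"

    def __post_init__(self):
        for name in ("times_s", "values", "valid"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.times_s) == len(self.values) == len(self.valid)):
            raise ValueError("trace arrays must have equal length")
        if self.kind not in ("heart", "breathing"):
            raise ValueError("kind must be 'heart' or 'breathing'")

    @classmethod
    def constant(cls, value: float, n_seconds: int, kind: str) -> "VitalsTrace":
        return cls(np.arange(n_seconds), np.full(n_seconds, float(value)),
                   np.ones(n_seconds, dtype=bool), kind)


@dataclass(frozen=True)
class RateError:
    mean_abs_error: float
    n_seconds: int


def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float,
              order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    sos = butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sosfiltfilt(sos, x)


def _lowpass(x: np.ndarray, cutoff: float, fs: float,
             order: int = 2) -> np.ndarray:
    sos = butter(order, cutoff / (fs / 2.0), btype="lowpass", output="sos")
    return sosfiltfilt(sos, x)


def homomorphic_envelope(x: np.ndarray, fs: float, lp_hz: float = 8.0,
                         env_fs: float = 50.0) -> tuple[np.ndarray, float]:
    """Smoothed log-magnitude envelope, decimated to ``env_fs`` Hz."""
    mag = np.abs(hilbert(x))
    env = np.exp(_lowpass(np.log(mag + 1e-10), lp_hz, fs))
    step = max(1, int(round(fs / env_fs)))
    return env[::step], fs / step


def heart_rate_trace(signal: AudioSignal, window_s: float = 5.0,
                     rate_range_bpm: tuple[float, float] = (90.0, 230.0),
                     min_periodicity: float = 0.2,
                     subharmonic_tolerance: float = 0.85) -> VitalsTrace:
    """Per-second heart rate from envelope autocorrelation.

    Seconds are flagged invalid when the best autocorrelation peak in
    the admissible lag range is weaker than ``min_periodicity`` times
    the zero-lag value (no credible periodicity, e.g. silence).  The
    period at an integer multiple of the true beat period correlates
    almost as strongly as the true one, so among peaks within
    ``subharmonic_tolerance`` of the strongest the *shortest* lag is
    taken (octave-error suppression).
    """
    fs = signal.sample_rate_hz
    if signal.duration_s < window_s:
        raise ValueError(f"need at least {window_s} s of audio")
    x = _bandpass(signal.samples, 50.0, 250.0, fs)
    peak = float(np.max(np.abs(x)))
    if peak > 0.0:
        x = x / peak           # exact amplitude invariance of the estimate
    env, efs = homomorphic_envelope(x, fs, env_fs=200.0)
    n_sec = int(signal.duration_s)
    times = np.arange(n_sec)
    values = np.zeros(n_sec)
    valid = np.zeros(n_sec, dtype=bool)
    # Search slightly beyond the admissible range so boundary rates
    # still produce a detectable interior peak; reject afterwards.
    lag_min = max(2, int(np.floor(efs * 60.0 / (rate_range_bpm[1] * 1.10))))
    lag_max = int(np.ceil(efs * 60.0 / (rate_range_bpm[0] * 0.92)))
    half = window_s / 2.0
    for sec in range(n_sec):
        center = sec + 0.5
        lo = int(max(0.0, center - half) * efs)
        hi = int(min(signal.duration_s, center + half) * efs)
        seg = env[lo:hi]
        seg = seg - seg.mean()
        denom = float(seg @ seg)
        if denom <= 0.0 or len(seg) <= lag_max:
            continue
        ac = np.correlate(seg, seg, mode="full")[len(seg) - 1:]
        ac = ac / denom
        window = ac[lag_min:lag_max + 1]
        peaks, _ = find_peaks(window)
        if len(peaks) == 0:
            continue
        vmax = float(np.max(window[peaks]))
        if vmax < min_periodicity:
            continue
        best = min(p for p in peaks
                   if window[p] >= subharmonic_tolerance * vmax)
        lag = float(lag_min + best)
        if 0 < best < len(window) - 1:  # parabolic refinement
            y0, y1, y2 = window[best - 1], window[best], window[best + 1]
            denom2 = y0 - 2 * y1 + y2
            if denom2 < 0:
                lag += 0.5 * (y0 - y2) / denom2
        rate = 60.0 * efs / lag
        if rate_range_bpm[0] <= rate <= rate_range_bpm[1]:
            values[sec] = rate
            valid[sec] = True
    return VitalsTrace(times, values, valid, "heart")


def breathing_rate_trace(signal: AudioSignal, window_s: float = 20.0,
                         band_hz: tuple[float, float] = (300.0, 450.0),
                         rate_range_brpm: tuple[float, float] = (15.0, 100.0),
                         env_lp_hz: float = 2.0,
                         min_prominence: float = 0.15,
                         min_modulation: float = 0.5) -> VitalsTrace:
    """Per-second breathing rate by peak detection on the band-power envelope.

    A second is flagged invalid when the envelope in its analysis
    window shows no real respiratory modulation — its 10th-90th
    percentile spread is below ``min_modulation`` times its median —
    so stationary band noise yields an invalid trace rather than a
    fabricated rate.
    """
    fs = signal.sample_rate_hz
    if signal.duration_s < window_s:
        raise ValueError(f"need at least {window_s} s of audio")
    x = _bandpass(signal.samples, band_hz[0], band_hz[1], fs)
    power = x ** 2
    env = _lowpass(power, env_lp_hz, fs)
    efs = 50.0
    step = max(1, int(round(fs / efs)))
    env = np.maximum(env[::step], 0.0)
    efs = fs / step
    n_sec = int(signal.duration_s)
    times = np.arange(n_sec)
    values = np.zeros(n_sec)
    valid = np.zeros(n_sec, dtype=bool)
    min_dist = int(efs * 60.0 / rate_range_brpm[1])
    half = window_s / 2.0
    for sec in range(n_sec):
        center = sec + 0.5
        lo = int(max(0.0, center - half) * efs)
        hi = int(min(signal.duration_s, center + half) * efs)
        seg = env[lo:hi]
        span = float(seg.max() - seg.min())
        med = float(np.median(seg))
        if span <= 0.0 or med <= 0.0:
            continue
        q10, q90 = np.percentile(seg, [10.0, 90.0])
        if (q90 - q10) / med < min_modulation:
            continue
        seg_n = (seg - seg.min()) / span
        peaks, _ = find_peaks(seg_n, prominence=min_prominence,
                              distance=max(1, min_dist))
        if len(peaks) < 2:
            continue
        # mean inter-breath interval over the window
        rate = 60.0 * efs / float(np.mean(np.diff(peaks)))
        if not (rate_range_brpm[0] <= rate <= rate_range_brpm[1]):
            continue
        values[sec] = rate
        valid[sec] = True
    return VitalsTrace(times, values, valid, "breathing")


def rate_error(trace: VitalsTrace, reference: VitalsTrace) -> RateError:
    """Mean absolute per-second difference over mutually valid seconds."""
    if trace.kind != reference.kind:
        raise ValueError("traces measure different vital signs")
    n = min(len(trace.times_s), len(reference.times_s))
    if n == 0:
        raise ValueError("traces do not overlap")
    both = trace.valid[:n] & reference.valid[:n]
    if not np.any(both):
        raise ValueError("no seconds valid in both traces")
    diff = np.abs(trace.values[:n][both] - reference.values[:n][both])
    return RateError(float(diff.mean()), int(both.sum()))


def rate_improvement(mixture: AudioSignal, separated: AudioSignal,
                     reference: VitalsTrace, kind: str) -> float:
    """Error(mixture) - error(separated); positive means separation helped."""
    tracer = heart_rate_trace if kind == "heart" else breathing_rate_trace
    err_mix = rate_error(tracer(mixture), reference).mean_abs_error
    err_sep = rate_error(tracer(separated), reference).mean_abs_error
    return err_mix - err_sep
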