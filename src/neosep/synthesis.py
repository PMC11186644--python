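"""Synthetic neonatal chest-sound generation with known ground truth.

Clinical neonatal chest recordings are not publicly available, so this
module generates surrogate sources that preserve the acoustic structure
the separation task exploits:

* **Heart sounds** — a periodic train of S1/S2 tone bursts.  Neonatal
  heart sounds occupy roughly the 50-250 Hz band; each beat contributes
  an S1 burst at the start of systole and a weaker S2 burst a fixed
  fraction of the beat period later.  Beat-to-beat jitter is
  multiplicative.
* **Lung sounds** — band-limited Gaussian noise in the 200-1000 Hz
  band, amplitude-modulated by the respiratory cycle (inspiration
  louder than expiration).
* **Noise classes** — spectral/temporal caricatures of the four
  contaminants found in the neonatal intensive-care unit: crying
  (harmonic bursts), stethoscope movement (sparse broadband
  transients), bubble-CPAP (periodic low-rate bubbling) and
  ventilator-CPAP (stationary hum plus broadband pedestal).

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio import WORKING_RATE_HZ, AudioSignal

NOISE_CLASSES = ("cry", "stethoscope_movement", "bubble_cpap", "ventilator_cpap")

#: Noise classes by evaluation partition.
GENERAL_NOISE_CLASSES = ("cry", "stethoscope_movement")
RESPIRATORY_NOISE_CLASSES = ("bubble_cpap", "ventilator_cpap")


@dataclass(frozen=True)
class HeartParams:
    """Parameters of the synthetic phonocardiogram.

    ``rate_bpm`` is the heart rate; S1/S2 spectral centers must lie in
    the neonatal heart-sound band (50-250 Hz); ``systole_fraction`` is
    the S1->S2 delay as a fraction of the beat period;
    ``beat_jitter_frac`` is the std of multiplicative beat-period
    jitter; S2 amplitude is ``amplitude_ratio_s2_s1`` times S1.
    """

    rate_bpm: float = 150.0
    s1_center_hz: float = 110.0
    s2_center_hz: float = 150.0
    systole_fraction: float = 0.35
    beat_jitter_frac: float = 0.02
    amplitude_ratio_s2_s1: float = 0.7

    def __post_init__(self):
        if self.rate_bpm <= 0:
            raise ValueError("rate_bpm must be positive")
        for f in (self.s1_center_hz, self.s2_center_hz):
            if not (50.0 <= f <= 250.0):
                raise ValueError("S1/S2 centers must lie in 50-250 Hz")
        if not (0.0 < self.systole_fraction < 1.0):
            raise ValueError("systole_fraction must be in (0, 1)")
        if self.beat_jitter_frac < 0:
            raise ValueError("beat_jitter_frac must be >= 0")
        if self.amplitude_ratio_s2_s1 <= 0:
            raise ValueError("amplitude_ratio_s2_s1 must be positive")


@dataclass(frozen=True)
class LungParams:
    """Parameters of the synthetic lung sound.

    The band must sit inside the neonatal lung-sound range
    (200-1000 Hz); ``rate_brpm`` is the respiratory rate;
    ``insp_exp_ratio`` shapes the within-cycle asymmetry;
    ``modulation_depth`` in [0, 1] controls how strongly respiration
    modulates the band noise (0 = stationary).
    """

    rate_brpm: float = 50.0
    band_low_hz: float = 200.0
    band_high_hz: float = 1000.0
    insp_exp_ratio: float = 1.5
    modulation_depth: float = 0.8

    def __post_init__(self):
        if self.rate_brpm <= 0:
            raise ValueError("rate_brpm must be positive")
        if not (self.band_low_hz < self.band_high_hz):
            raise ValueError("band_low_hz must be < band_high_hz")
        if self.insp_exp_ratio <= 0:
            raise ValueError("insp_exp_ratio must be positive")
        if not (0.0 <= self.modulation_depth <= 1.0):
            raise ValueError("modulation_depth must be in [0, 1]")


@dataclass(frozen=True)
class NoiseClip:
    signal: AudioSignal
    noise_class: str

    def __post_init__(self):
        if self.noise_class not in NOISE_CLASSES:
            raise ValueError(f"unknown noise class {self.noise_class!r}; "
                             f"expected one of {NOISE_CLASSES}")


@dataclass(frozen=True)
class SourceSet:
    """Aligned heart and lung reference waveforms (the two targets)."""

    heart: AudioSignal
    lung: AudioSignal

    def __post_init__(self):
        if len(self.heart) != len(self.lung):
            raise ValueError("heart and lung must have equal length")
        if self.heart.sample_rate_hz != self.lung.sample_rate_hz:
            raise ValueError("heart and lung must share a sample rate")


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges for the source bank.

    Defaults cover the neonatal heart-rate range (90-230 bpm) and
    breathing-rate range (30-80 breaths/min).
    """

    heart_rate_bpm: tuple[float, float] = (90.0, 230.0)
    s1_center_hz: tuple[float, float] = (90.0, 140.0)
    s2_center_hz: tuple[float, float] = (130.0, 190.0)
    beat_jitter_frac: tuple[float, float] = (0.01, 0.04)
    breathing_rate_brpm: tuple[float, float] = (30.0, 80.0)
    lung_band_low_hz: tuple[float, float] = (200.0, 320.0)
    lung_band_high_hz: tuple[float, float] = (600.0, 1000.0)
    modulation_depth: tuple[float, float] = (0.6, 0.95)
    noise_classes: tuple[str, ...] = NOISE_CLASSES


def _bandpass(x: np.ndarray, lo: float, hi: float, rate_hz: int,
              order: int = 6) -> np.ndarray:
    nyq = rate_hz / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band [{lo}, {hi}] outside (0, {nyq}) Hz")
    sos = butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sosfiltfilt(sos, x)


def _tone_burst(t_rel: np.ndarray, center_hz: float, sigma_s: float,
                phase: float) -> np.ndarray:
    """Gaussian-windowed tone burst centered at t_rel = 0."""
    return np.exp(-0.5 * (t_rel / sigma_s) ** 2) * np.cos(
        2 * np.pi * center_hz * t_rel + phase)


def synth_heart(duration_s: float, params: HeartParams = HeartParams(),
                rate_hz: int = WORKING_RATE_HZ, seed: int = 0,
                burst_sigma_s: float = 0.012) -> AudioSignal:
    """Synthesize a phonocardiogram: jittered periodic S1/S2 bursts.

    The first S1 is placed half a beat period into the recording, so a
    recording of ``duration_s`` seconds at rate ``r`` beats/min carries
    exactly ``floor(r * duration_s / 60)`` S1 events when jitter is 0.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    x = np.zeros(n)
    period = 60.0 / params.rate_bpm
    edge = 4.0 * burst_sigma_s  # keep whole bursts inside the recording
    t_beat = 0.5 * period
    while t_beat < duration_s - edge + 0.5 * period * 1e-9:
        this_period = period * max(
            0.1, 1.0 + params.beat_jitter_frac * rng.standard_normal())
        for center, center_hz, amp in (
                (t_beat, params.s1_center_hz, 1.0),
                (t_beat + params.systole_fraction * this_period,
                 params.s2_center_hz, params.amplitude_ratio_s2_s1)):
            if center >= duration_s - edge:
                continue
            lo = max(0, int((center - edge) * rate_hz))
            hi = min(n, int((center + edge) * rate_hz) + 1)
            x[lo:hi] += amp * _tone_burst(t[lo:hi] - center, center_hz,
                                          burst_sigma_s, 0.0)
        t_beat += this_period
    if np.max(np.abs(x)) > 0:
        x = x / np.max(np.abs(x))
    return AudioSignal(x, rate_hz)


def _respiratory_envelope(t: np.ndarray, rate_brpm: float,
                          insp_exp_ratio: float, depth: float) -> np.ndarray:
    """Respiration amplitude envelope in [1 - depth, 1].

    Each breath cycle rises during inspiration and falls during
    expiration; ``insp_exp_ratio`` sets the duration ratio of the two
    segments via a phase warp of a raised cosine.
    """
    cycle_s = 60.0 / rate_brpm
    phase = (t / cycle_s) % 1.0
    split = insp_exp_ratio / (1.0 + insp_exp_ratio)
    warped = np.where(phase < split, 0.5 * phase / split,
                      0.5 + 0.5 * (phase - split) / (1.0 - split))
    resp = 0.5 * (1.0 - np.cos(2 * np.pi * warped))  # 0..1, peak at end of insp.
    return (1.0 - depth) + depth * resp


def synth_lung(duration_s: float, params: LungParams = LungParams(),
               rate_hz: int = WORKING_RATE_HZ, seed: int = 0) -> AudioSignal:
    """Synthesize a lung sound: respiration-modulated band noise."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    noise = _bandpass(rng.standard_normal(n), params.band_low_hz,
                      params.band_high_hz, rate_hz)
    t = np.arange(n) / rate_hz
    env = _respiratory_envelope(t, params.rate_brpm, params.insp_exp_ratio,
                                params.modulation_depth)
    x = noise * env
    x = x / np.max(np.abs(x))
    return AudioSignal(x, rate_hz)


def _synth_cry(n: int, rate_hz: int, rng: np.random.Generator) -> np.ndarray:
    """Harmonic bursts with on/off gating, fundamental 350-600 Hz."""
    t = np.arange(n) / rate_hz
    x = np.zeros(n)
    pos = rng.uniform(0.0, 0.6)
    while pos < n / rate_hz:
        burst_len = rng.uniform(0.4, 1.2)
        f0 = rng.uniform(350.0, 600.0)
        lo = int(pos * rate_hz)
        hi = min(n, int((pos + burst_len) * rate_hz))
        if hi > lo:
            tt = t[lo:hi] - pos
            seg = np.zeros(hi - lo)
            for h in range(1, 4):
                if h * f0 < rate_hz / 2 * 0.95:
                    seg += (1.0 / h) * np.sin(
                        2 * np.pi * h * f0 * tt + rng.uniform(0, 2 * np.pi))
            ramp = min(0.05, burst_len / 4)
            w = np.minimum(1.0, np.minimum(tt, burst_len - tt) / ramp)
            x[lo:hi] += seg * np.clip(w, 0.0, 1.0)
        pos += burst_len + rng.uniform(0.3, 1.5)
    return x


def _synth_stethoscope(n: int, rate_hz: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Sparse broadband transients; quiet for most of the recording."""
    x = np.zeros(n)
    n_events = max(1, int(rng.poisson(0.8 * n / rate_hz)))
    for _ in range(n_events):
        start = rng.integers(0, max(1, n - 1))
        length = int(rng.uniform(0.03, 0.15) * rate_hz)
        hi = min(n, start + length)
        burst = rng.standard_normal(hi - start)
        decay = np.exp(-np.arange(hi - start) / (0.03 * rate_hz))
        x[start:hi] += burst * decay * rng.uniform(0.5, 1.0)
    return x


def _synth_bubble(n: int, rate_hz: int, rng: np.random.Generator,
                  bubble_rate_hz: float | None = None) -> np.ndarray:
    """Bubble-CPAP surrogate: filtered noise gated at 8-30 Hz repetition."""
    if bubble_rate_hz is None:
        bubble_rate_hz = rng.uniform(8.0, 30.0)
    t = np.arange(n) / rate_hz
    gate = 0.5 * (1.0 + np.cos(2 * np.pi * bubble_rate_hz * t)) ** 2
    carrier = _bandpass(rng.standard_normal(n), 60.0, 400.0, rate_hz, order=4)
    return carrier * (0.2 + 0.8 * gate)


def _synth_ventilator(n: int, rate_hz: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Ventilator-CPAP surrogate: stationary tonal hum + broadband pedestal."""
    t = np.arange(n) / rate_hz
    hum_hz = rng.uniform(80.0, 160.0)
    hum = np.sin(2 * np.pi * hum_hz * t + rng.uniform(0, 2 * np.pi))
    hum += 0.4 * np.sin(2 * np.pi * 2 * hum_hz * t + rng.uniform(0, 2 * np.pi))
    pedestal = _bandpass(rng.standard_normal(n), 100.0, 1200.0, rate_hz,
                         order=4)
    return hum + 0.6 * pedestal


def synth_noise(duration_s: float, noise_class: str,
                rate_hz: int = WORKING_RATE_HZ, seed: int = 0,
                **kwargs) -> NoiseClip:
    """Generate one noise clip of the given class; deterministic per seed."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if noise_class not in NOISE_CLASSES:
        raise ValueError(f"unknown noise class {noise_class!r}; "
                         f"expected one of {NOISE_CLASSES}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    if noise_class == "cry":
        x = _synth_cry(n, rate_hz, rng)
    elif noise_class == "stethoscope_movement":
        x = _synth_stethoscope(n, rate_hz, rng)
    elif noise_class == "bubble_cpap":
        x = _synth_bubble(n, rate_hz, rng, kwargs.get("bubble_rate_hz"))
    else:
        x = _synth_ventilator(n, rate_hz, rng)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return NoiseClip(AudioSignal(x, rate_hz), noise_class)


def make_source_bank(n: int, duration_s: float = 10.0,
                     rate_hz: int = WORKING_RATE_HZ, seed: int = 0,
                     param_ranges: ParamRanges = ParamRanges()
                     ) -> list[tuple[SourceSet, NoiseClip]]:
    """Draw ``n`` independent (SourceSet, NoiseClip) pairs.

    Heart/lung parameters are sampled uniformly from ``param_ranges``;
    the noise class is drawn uniformly from ``param_ranges.noise_classes``.
    Per-example seeds are derived by counter-based spawning so each
    example is independent of the others and of their order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    bank: list[tuple[SourceSet, NoiseClip]] = []
    for child in root.spawn(n):
        s_heart, s_lung, s_noise, s_params = child.spawn(4)
        rng = np.random.default_rng(s_params)
        pr = param_ranges
        hp = HeartParams(
            rate_bpm=rng.uniform(*pr.heart_rate_bpm),
            s1_center_hz=rng.uniform(*pr.s1_center_hz),
            s2_center_hz=rng.uniform(*pr.s2_center_hz),
            beat_jitter_frac=rng.uniform(*pr.beat_jitter_frac),
        )
        lp = LungParams(
            rate_brpm=rng.uniform(*pr.breathing_rate_brpm),
            band_low_hz=rng.uniform(*pr.lung_band_low_hz),
            band_high_hz=rng.uniform(*pr.lung_band_high_hz),
            modulation_depth=rng.uniform(*pr.modulation_depth),
        )
        noise_class = str(rng.choice(list(pr.noise_classes)))
        heart = synth_heart(duration_s, hp, rate_hz,
                            seed=int(s_heart.generate_state(1)[0] % 2**31))
        lung = synth_lung(duration_s, lp, rate_hz,
                          seed=int(s_lung.generate_state(1)[0] % 2**31))
        noise = synth_noise(duration_s, noise_class, rate_hz,
                            seed=int(s_noise.generate_state(1)[0] % 2**31))
        bank.append((SourceSet(heart, lung), noise))
    return bank


def in_band_power_fraction(signal: AudioSignal, lo_hz: float,
                           hi_hz: float) -> float:
    """Fraction of Welch-spectrum power inside [lo_hz, hi_hz]."""
    from scipy.signal import welch
    nper = min(len(signal), 2048)
    f, pxx = welch(signal.samples, fs=signal.sample_rate_hz, nperseg=nper)
    total = np.trapezoid(pxx, f)
    band = (f >= lo_hz) & (f <= hi_hz)
    return float(np.trapezoid(pxx[band], f[band]) / total)
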