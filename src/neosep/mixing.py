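"""Mixture assembly: relative-power scaling, convolutive FIR channels,
random cropping and the two-phase noise curriculum.

A mixture is ``heart + lung' + noise'`` where the lung and noise stems
are rescaled to a drawn relative signal power (in dB, with the heart
stem as the 0 dB anchor) and optionally passed through a short random
FIR channel.  The stored references are the stems *as present in the
mixture* (post-filter, post-scale), so the training targets are exactly
what the network can recover.

The curriculum has two phases: pretraining with noise at -20..0 dB
relative power, then fine-tuning with noise at -10..10 dB.  Stethoscope
movement noise is excluded from training builds but kept in test
builds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .audio import AudioSignal, write_audio
from .synthesis import (GENERAL_NOISE_CLASSES, NOISE_CLASSES,
                        RESPIRATORY_NOISE_CLASSES, NoiseClip, SourceSet)

PARTITIONS = ("no_noise", "general_noise", "respiratory_support")


def partition_for(noise_class: str | None) -> str:
    """Evaluation partition implied by the noise class."""
    if noise_class is None:
        return "no_noise"
    if noise_class in GENERAL_NOISE_CLASSES:
        return "general_noise"
    if noise_class in RESPIRATORY_NOISE_CLASSES:
        return "respiratory_support"
    raise ValueError(f"unknown noise class {noise_class!r}")


@dataclass(frozen=True)
class CurriculumPhase:
    """One phase of the noise curriculum (dB ranges are closed intervals)."""

    name: str
    noise_db_range: tuple[float, float]
    lung_db_range: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self):
        for rng_ in (self.noise_db_range, self.lung_db_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"inverted dB range {rng_}")


#: Noise rescaled to -20..0 dB so the model first learns heart/lung identity.
PRETRAIN = CurriculumPhase("pretrain", (-20.0, 0.0))
#: Harder fine-tuning phase with noise up to +10 dB relative power.
FINETUNE = CurriculumPhase("finetune", (-10.0, 10.0))


@dataclass(frozen=True)
class MixOptions:
    """Knobs of mixture assembly.

    ``convolutive_prob`` is the probability that the lung stem (and,
    independently, the noise stem) passes through a random FIR channel
    of length drawn from ``fir_length_range``.  ``p_no_noise`` is the
    probability an example is built without any noise stem.
    ``exclude_noise_classes`` lists classes never used (training builds
    exclude stethoscope movement).
    """

    convolutive_prob: float = 0.5
    fir_length_range: tuple[int, int] = (3, 5)
    p_no_noise: float = 0.25
    exclude_noise_classes: tuple[str, ...] = ()
    peak_guard: bool = True


@dataclass(frozen=True)
class MixtureExample:
    mixture: AudioSignal
    references: SourceSet
    noise_class: str | None
    noise_rel_db: float | None
    lung_rel_db: float
    filter_len: int | None
    partition: str
    noise_reference: AudioSignal | None = None

    def __post_init__(self):
        if self.partition != partition_for(self.noise_class):
            raise ValueError(
                f"partition {self.partition!r} inconsistent with noise class "
                f"{self.noise_class!r}")
        if len(self.mixture) != len(self.references.heart):
            raise ValueError("mixture and references must have equal length")


def rescale_relative_power(x: AudioSignal, reference: AudioSignal,
                           target_db: float) -> AudioSignal:
    """Scale ``x`` so 10*log10(power(x')/power(reference)) = target_db."""
    px, pref = x.power(), reference.power()
    if px == 0.0 or pref == 0.0:
        raise ValueError("cannot rescale with a zero-power signal")
    scale = np.sqrt(pref / px * 10.0 ** (target_db / 10.0))
    return x.replace(x.samples * scale)


def sample_relative_db(db_range: tuple[float, float],
                       rng: np.random.Generator) -> float:
    """Uniform draw from a closed dB interval."""
    lo, hi = db_range
    if lo > hi:
        raise ValueError(f"inverted dB range [{lo}, {hi}]")
    return float(rng.uniform(lo, hi))


def random_fir(length_range: tuple[int, int], rng: np.random.Generator
               ) -> np.ndarray:
    """Random unit-energy FIR taps with length uniform in the range.

    Taps are drawn zero-mean uniform then normalised so the filter is
    energy-preserving in expectation on white inputs.
    """
    lo, hi = length_range
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid FIR length range [{lo}, {hi}]")
    length = int(rng.integers(lo, hi + 1))
    taps = rng.uniform(-1.0, 1.0, length)
    norm = np.sqrt(np.sum(taps ** 2))
    while norm == 0.0:  # vanishing-probability degenerate draw
        taps = rng.uniform(-1.0, 1.0, length)
        norm = np.sqrt(np.sum(taps ** 2))
    return taps / norm


def apply_convolutive(x: AudioSignal, taps: np.ndarray) -> AudioSignal:
    """Linear convolution truncated to the input length ('same' head)."""
    taps = np.asarray(taps, dtype=np.float64)
    if taps.ndim != 1 or taps.size < 1:
        raise ValueError("taps must be a non-empty 1-D array")
    out = np.convolve(x.samples, taps)[:len(x)]
    return x.replace(out)


def random_crop(signals: list[AudioSignal], crop_s: float,
                rng: np.random.Generator) -> list[AudioSignal]:
    """Crop all signals with one shared uniformly-random start offset."""
    if not signals:
        raise ValueError("no signals to crop")
    n = len(signals[0])
    rate = signals[0].sample_rate_hz
    for s in signals:
        if len(s) != n or s.sample_rate_hz != rate:
            raise ValueError("signals must be aligned (same length and rate)")
    crop_n = int(round(crop_s * rate))
    if crop_n > n:
        raise ValueError(f"crop of {crop_n} samples exceeds input length {n}")
    start = int(rng.integers(0, n - crop_n + 1))
    return [s.replace(s.samples[start:start + crop_n]) for s in signals]


def compose_mixture(sources: SourceSet, noise: NoiseClip | None,
                    phase: CurriculumPhase,
                    options: MixOptions = MixOptions(),
                    rng: np.random.Generator | None = None) -> MixtureExample:
    """Assemble one mixture example.

    The heart stem is the 0 dB anchor.  The lung stem is rescaled by a
    draw from ``phase.lung_db_range``; the noise stem (if any) by a
    draw from ``phase.noise_db_range``.  Random FIR channels are
    applied to lung/noise independently with ``options.convolutive_prob``
    *before* power scaling, and the stored references are the processed
    stems, so the mixture is exactly the sum of its references (plus
    noise).  If ``options.peak_guard`` and the mixture peak exceeds 1,
    everything is scaled down by the same constant (relative powers are
    unchanged).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    heart, lung = sources.heart, sources.lung
    if noise is not None and len(noise.signal) != len(heart):
        raise ValueError("noise and sources must have equal length")

    filter_len: int | None = None

    def maybe_filter(sig: AudioSignal) -> tuple[AudioSignal, int | None]:
        if rng.uniform() < options.convolutive_prob:
            taps = random_fir(options.fir_length_range, rng)
            return apply_convolutive(sig, taps), int(taps.size)
        return sig, None

    lung2, _ = maybe_filter(lung)
    lung_rel_db = sample_relative_db(phase.lung_db_range, rng)
    lung2 = rescale_relative_power(lung2, heart, lung_rel_db)

    noise_rel_db: float | None = None
    noise2: AudioSignal | None = None
    if noise is not None:
        noise2, filter_len = maybe_filter(noise.signal)
        noise_rel_db = sample_relative_db(phase.noise_db_range, rng)
        noise2 = rescale_relative_power(noise2, heart, noise_rel_db)

    mix = heart.samples + lung2.samples
    if noise2 is not None:
        mix = mix + noise2.samples

    scale = 1.0
    if options.peak_guard:
        peak = float(np.max(np.abs(mix)))
        if peak > 1.0:
            scale = 1.0 / peak
    mixture = AudioSignal(mix * scale, heart.sample_rate_hz)
    refs = SourceSet(heart.replace(heart.samples * scale),
                     lung2.replace(lung2.samples * scale))
    noise_ref = (noise2.replace(noise2.samples * scale)
                 if noise2 is not None else None)
    noise_class = noise.noise_class if noise is not None else None
    return MixtureExample(
        mixture=mixture, references=refs, noise_class=noise_class,
        noise_rel_db=noise_rel_db, lung_rel_db=lung_rel_db,
        filter_len=filter_len, partition=partition_for(noise_class),
        noise_reference=noise_ref)


def build_training_set(bank: list[tuple[SourceSet, NoiseClip]],
                       phase: CurriculumPhase,
                       options: MixOptions | None = None,
                       seed: int = 0,
                       training: bool = True) -> list[MixtureExample]:
    """Compose one mixture per bank entry, reproducibly.

    Training builds exclude stethoscope-movement noise (an excluded
    example's noise class is redrawn from the remaining classes using
    its own substream); test builds keep all four classes.  With
    probability ``options.p_no_noise`` an example carries no noise at
    all, so every evaluation partition is populated.
    """
    if not bank:
        raise ValueError("empty source bank")
    if options is None:
        options = MixOptions(
            exclude_noise_classes=("stethoscope_movement",) if training else ())
    elif training and "stethoscope_movement" not in options.exclude_noise_classes:
        options = replace(
            options, exclude_noise_classes=options.exclude_noise_classes
            + ("stethoscope_movement",))

    root = np.random.SeedSequence(entropy=(seed, 0xA5))
    examples: list[MixtureExample] = []
    for child, (sources, noise) in zip(root.spawn(len(bank)), bank):
        rng = np.random.default_rng(child)
        use_noise: NoiseClip | None = noise
        if rng.uniform() < options.p_no_noise:
            use_noise = None
        elif noise.noise_class in options.exclude_noise_classes:
            allowed = [c for c in NOISE_CLASSES
                       if c not in options.exclude_noise_classes]
            new_class = str(rng.choice(allowed))
            from .synthesis import synth_noise
            use_noise = synth_noise(
                sources.heart.duration_s, new_class,
                sources.heart.sample_rate_hz,
                seed=int(rng.integers(0, 2**31)))
        examples.append(compose_mixture(sources, use_noise, phase, options, rng))
    return examples


def write_dataset(examples: list[MixtureExample], root: Path,
                  split: str = "train") -> Path:
    """Write ``<root>/<split>/<id>/{mixture,heart,lung,noise}.wav`` + manifest."""
    import pandas as pd
    root = Path(root)
    rows = []
    for i, ex in enumerate(examples):
        d = root / split / f"{i:04d}"
        d.mkdir(parents=True, exist_ok=True)
        write_audio(ex.mixture, d / "mixture.wav")
        write_audio(ex.references.heart, d / "heart.wav")
        write_audio(ex.references.lung, d / "lung.wav")
        if ex.noise_reference is not None:
            write_audio(ex.noise_reference, d / "noise.wav")
        rows.append({
            "example_id": f"{i:04d}", "partition": ex.partition,
            "noise_class": ex.noise_class or "",
            "noise_rel_db": ex.noise_rel_db, "lung_rel_db": ex.lung_rel_db,
            "filter_len": ex.filter_len,
        })
    manifest = root / split / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
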