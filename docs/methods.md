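# Methods

## Problem and model

Neonatal chest recordings mix heart sounds (roughly 50-250 Hz, periodic
S1/S2 transients), lung sounds (roughly 200-1000 Hz broadband noise
modulated by respiration) and ward noise (crying, stethoscope movement,
bubble-CPAP and ventilator-CPAP machinery).  `neosep` separates a mono
4 kHz recording into aligned heart and lung waveforms with a
mask-based learned-codec network:

* **Encoder** — a strided 1-D convolution maps the waveform `(1, T)`
  to a feature map `(F, M)`; a ReLU keeps the "token" representation
  non-negative, following the learned-basis convention of
  time-domain separation networks.  With kernel `K` and stride `S`,
  `M = floor((T - K)/S) + 1`.
* **Mask generator** — a pointwise projection to the mask feature
  width, a stack of residual convolution blocks (same-padded conv,
  channel layer norm, PReLU), sinusoidal positional encoding, a stack
  of pre-norm transformer blocks (multi-head self-attention + GELU
  feed-forward), and a pointwise projection to `s*F` channels with a
  sigmoid, giving one bounded mask per source, `(2, F, M)`.
* **Decoder** — a transposed 1-D convolution returns each masked
  feature map to a waveform, trimmed/zero-padded to the input length.

Source identity is fixed by output index (0 = heart, 1 = lung); the
targets are labeled, so no permutation-invariant training is needed.
The final-model hyperparameters are kernel 512, feature size 512, mask
feature size 256, conv kernel 3 with 6 conv layers, 4 heads and 4
transformer layers.  The encoder hop is not part of the published
recipe; the default here is 50% overlap (stride = kernel/2), the
standard learned-codec choice.  Internal block details (pre-norm
residuals, feed-forward multiplier 4, positional encoding, PReLU conv
blocks) are likewise this package's choices, all exposed in
`ModelConfig`.  With them the full configuration counts 5.26 M
parameters (`count_parameters`); the original system reports 8.42 M,
so its unpublished internals are somewhat wider — the count here is
documented per configuration rather than matched.

Encoder and decoder carry biases (the conv-layer default), so the
codec path is affine rather than strictly linear; tests treat it as
linear about its zero-input response.

An **STFT codec** ablation replaces encoder/decoder with fixed
windowed-DFT kernels (periodic Hann, constant-overlap-add verified at
construction).  It is expressed with the same convolution primitives,
so it remains differentiable; masks multiply the magnitude features
and reconstruction uses the mixture phase.  With all-ones masks the
round trip is exact to floating-point precision.

## Objective and training recipe

Training maximises the scale-invariant signal-to-distortion ratio per
source:

    alpha   = <s_est, s_target> / ||s_target||^2
    e_noise = alpha s_target - s_est
    SI-SDR  = 10 log10( ||alpha s_target||^2 / ||e_noise||^2 )

The loss is the negative mean over the two sources.  Per-source
SI-SDR is clamped to ±60 dB: an exact match is otherwise +inf, and the
clamp (with zero gradient outside the band) keeps optimisation stable.
The optimiser is AdamW with the AMSGrad correction, weight decay 0.1,
initial learning rate 1e-4, beta = (0.9, 0.999); gradients are clipped
to a global L2 norm of 5; the learning rate is halved when the
validation metric — mean validation SI-SDR over both sources, the
package's reading of "validation accuracy" — fails to improve for 4
consecutive epochs.  Batches of 16 draw a fresh random 8-s crop
(32,000 samples of the 40,000-sample recordings) of every example each
epoch, an augmentation reading of the random-crop rule that maximises
effective dataset size.  The curriculum has two phases: pretraining
with noise rescaled to −20..0 dB relative power, fine-tuning with
−10..10 dB; the epoch split (30 + 10 of 40 by default) is not
published and is config-exposed.  Best-validation parameters are
checkpointed.

The whole network and its optimiser run on a compact numpy
reverse-mode autodiff tape (`neosep.tensor`, `neosep.nn`) written for
this package; every backward rule is verified against central finite
differences in the test suite, and training is bitwise reproducible
per seed.

## Synthetic data

The clinical recordings behind the original study are not public, so
`neosep.synthesis` generates surrogates that preserve what the
separation task exploits — band structure and periodicity — and no
more (no murmurs, crackles or wheeze taxonomy):

* Heart: Gaussian-windowed tone bursts (sigma 12 ms) at S1
  (default 110 Hz) and S2 (default 150 Hz, amplitude 0.7 of S1,
  delayed by 0.35 of the beat period), with multiplicative
  beat-period jitter.  The first S1 sits half a period in, so a
  jitter-free recording carries exactly `floor(rate * duration / 60)`
  beats.  At least 95% of power falls in 40-300 Hz.
* Lung: band-passed Gaussian noise (default 200-1000 Hz, order-6
  Butterworth) amplitude-modulated by an asymmetric raised-cosine
  respiratory cycle (inspiration/expiration ratio 1.5, modulation
  depth 0.8 by default); at least 90% of power stays in band.
* Noise classes: cry (gated harmonic bursts, fundamental 350-600 Hz),
  stethoscope movement (sparse decaying broadband transients, quiet
  ≥50% of the time), bubble-CPAP (band noise gated at 8-30 Hz
  repetition), ventilator-CPAP (tonal hum plus broadband pedestal).
  These are spectral/temporal caricatures: the real recordings are
  not quantitatively characterised in print.

Source banks sample heart rate uniformly in 90-230 bpm (neonatal
range) and breathing rate in 30-80 breaths/min, with per-example
substreams spawned from one master seed so examples are
order-independent.

Mixtures anchor relative power at the heart stem (0 dB): the common
element of every mixture, matching the convention of the lineage of
datasets this one descends from.  The lung level is drawn from
−10..10 dB (not published; config-exposed), the noise level from the
phase's curriculum range.  Unit-energy random FIR channels of length
3-5 are applied to the lung and noise stems independently with
probability 0.5 (the published recipe states only the length range);
references are stored post-filter and post-scale, so the mixture is
exactly the sum of its references and the targets are what is actually
present.  A quarter of examples carry no noise so every evaluation
partition (no-noise / general / respiratory-support) is populated.
Stethoscope movement is excluded from training builds and kept in test
builds.  If a mixture's peak exceeds 1, mixture and references are
scaled by the same constant (relative powers unchanged).

Because the generators are caricatures, passing tests demonstrate that
the pipeline learns and measures what it should on signals with the
stated band/periodicity structure; they do not establish clinical
performance, which the original study measures on real recordings.

## Evaluation

`neosep.metrics` decomposes an estimate as
`s_est = s_target + e_interf + e_noise + e_artif` by successive
orthogonal projections onto the span of the target, of target plus the
other source, and of those plus the noise (pseudo-inverse for
degenerate spans).  The projections are whole-signal subspace
projections (allowed distortion = a single gain): exactly testable by
hand.  The classic toolkits instead allow 512-tap filters; with the
scalar variant SDR coincides with SI-SDR by construction, which the
summary tables make visible.  Improvements (SDRi, SI-SDRi) subtract
the same metric computed with the unprocessed mixture as the estimate.
Medians and linear-interpolation quartiles are reported per partition
and source.

## Vital-sign estimation

The heart-rate estimator band-passes to 50-250 Hz, peak-normalises
(exact amplitude invariance), takes a homomorphic envelope (8 Hz
low-pass of the log magnitude, exponentiated, decimated to 200 Hz) and
searches the envelope autocorrelation of a 5-s sliding window for the
beat period within 90-230 bpm.  Integer multiples of the true period
correlate almost as strongly as the period itself, so among peaks
within 85% of the strongest the shortest lag wins (octave-error
suppression), with parabolic lag refinement.  This is the envelope/
periodicity front-end of the HSMM-based segmenters; the decoding stage
needs trained emission models that are not published, so it is not
reproduced.  The breathing-rate estimator band-passes to 300-450 Hz,
low-passes the power envelope at 2 Hz and counts peaks over a 20-s
window, limited to 15-100 breaths/min; windows whose envelope
10th-90th percentile spread is below half its median show no real
respiratory modulation and are flagged invalid.  Rate errors average
absolute per-second differences over seconds valid in both traces;
`rate_improvement` is error(mixture) − error(separated).

## Scaled-down experiment

The full-scale recipe is out of reach at desk scale, so the canned
experiment (`neosep.experiments.run_scaled_down`) trains the reduced
configuration — feature size 128, mask feature 64, 2 conv + 2
transformer layers, 2 heads — on 200 synthetic mixtures under the
pretraining curriculum, validates on 16 and scores 50 held-out
mixtures, all 10-s recordings at 4 kHz.  The reduced model trains
stably at a larger step size than the full-scale default, so the
recipe uses learning rate 5e-4 for 40 single-phase epochs (about five
minutes on one CPU).  Typical results (seed 0): median SI-SDR
improvement ≈ 14 dB for heart and ≈ 8 dB for lung over the 50 test
mixtures.

## Numerical choices and limitations

* Everything runs in float64; determinism holds for fixed seeds and
  identical BLAS kernels.
* dB ratios are clamped to ±60 throughout (loss and metrics agree to
  1e-9 dB on shared inputs).
* Degenerate inputs error rather than guess: all-zero signals for
  normalisation/rescaling, zero targets in SI-SDR, crops longer than
  the recording, inputs shorter than the encoder kernel, non-COLA
  STFT window/hop pairs.
* WAV I/O is float32 by default (lossless round trips in tests);
  16-bit PCM uses symmetric 32767 scaling so round trips stay within
  one quantisation step.  Compressed audio and multichannel
  separation are out of scope.
* Inference is single-buffer: recordings of any length at least the
  encoder kernel are processed whole.
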