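# neosep — neonatal chest-sound separation

Auscultation of newborns yields a single-channel mixture: heart sounds
(≈50–250 Hz, periodic S1/S2 transients), lung sounds (≈200–1000 Hz,
respiration-modulated noise) and ward noise — crying, stethoscope
movement, bubble- and ventilator-CPAP machinery.  Clinical algorithms
(rate monitoring, computer-aided diagnosis) want one source at a time.
`neosep` separates a mono 4 kHz chest recording into aligned heart and
lung waveforms, for researchers in biomedical signal processing who
need a tested, reproducible separation pipeline without access to
clinical recordings.

## Model

A mask-based learned-codec network in the Conv-TasNet family.  A
strided 1-D convolution encodes the waveform `(1, T)` into a feature
map `(F, M)`; a mask generator (residual conv blocks, then pre-norm
transformer blocks) emits one sigmoid mask per source, `(2, F, M)`;
each mask multiplies the features and a transposed convolution decodes
each product back to a waveform `(2, T)`.  Training maximises the
scale-invariant signal-to-distortion ratio per source,

```
α = ⟨ŝ, s⟩ / ‖s‖²,   e = αs − ŝ,   SI-SDR = 10 log₁₀(‖αs‖² / ‖e‖²),
```

with AdamW+AMSGrad (weight decay 0.1), gradient clipping at L2 norm 5,
plateau learning-rate halving (patience 4), fresh random 8-s crops
each epoch, and a two-phase noise curriculum (noise at −20..0 dB
relative power, then −10..10 dB).  Since the clinical dataset is not
public, the package ships generators for synthetic heart/lung/noise
sources with known ground truth; all training and evaluation run on
them.  The network and its optimiser run on a compact numpy
reverse-mode autodiff engine included in the package (gradients are
finite-difference-verified in the tests).  See `docs/methods.md` for
the full account.

## Worked example

```python
from neosep import (PRETRAIN, ModelConfig, Separator, TrainConfig,
                    build_training_set, si_sdr, train)
from neosep.synthesis import make_source_bank

bank = make_source_bank(40, duration_s=10.0, seed=0)      # 10 s @ 4 kHz
train_set = build_training_set(bank, PRETRAIN, seed=0, training=True)
val_set = build_training_set(make_source_bank(8, seed=1), PRETRAIN,
                             seed=1, training=False)
model = Separator(ModelConfig.small(), seed=0)
cfg = TrainConfig(epochs=12, pretrain_epochs=12, lr_init=5e-4, seed=0)
model, history = train(model, {"pretrain": train_set}, val_set, cfg)

ex = build_training_set(make_source_bank(1, seed=2), PRETRAIN,
                        seed=2, training=False)[0]
est = model.separate(ex.mixture)
for name, e, ref in (("heart", est.heart, ex.references.heart),
                     ("lung", est.lung, ex.references.lung)):
    print(name, si_sdr(ex.mixture, ref), "->", si_sdr(e, ref))
```

This two-minute run (`examples/03_train_and_separate.py`) prints, for
one held-out mixture:

```
heart: SI-SDR  +4.25 dB (mixture) -> +11.61 dB (separated), improvement +7.36 dB
lung: SI-SDR  -4.25 dB (mixture) ->  -1.87 dB (separated), improvement +2.39 dB
```

i.e. the heart estimate is ~7.4 dB closer to the true heart stem than
the raw mixture was, and the lung estimate ~2.4 dB closer — after
only a twelve-epoch demonstration run; lung quality keeps improving
with the full schedule.  The full
scaled-down experiment (`examples/04_evaluate_by_partition.py`; 200
training mixtures, 40 epochs, ~5 min on one CPU) reaches median
SI-SDR improvements of about 14 dB (heart) and 8 dB (lung) over 50
held-out mixtures.

The other examples cover the generators (`01`), mixture bookkeeping
(`02`) and vital-sign estimation (`05`).  A thin CLI wraps the same
library calls:

```
neosep synth --out data --n 10 --phase pretrain --seed 0
neosep train --out ckpt.npz --n-train 200 --seed 0
neosep separate --checkpoint ckpt.npz --in chest.wav \
                --heart-out heart.wav --lung-out lung.wav
neosep evaluate --checkpoint ckpt.npz --n-test 50 --out eval/
neosep vitals --in heart.wav --kind heart --out trace.csv
```

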