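"""Assemble training mixtures under the two-phase noise curriculum.

Shows the relative-power bookkeeping: the heart stem anchors 0 dB,
lung and noise are rescaled to drawn dB offsets, and the stored
references sum exactly to the mixture.
"""

import numpy as np

from neosep import PRETRAIN, build_training_set
from neosep.synthesis import make_source_bank

bank = make_source_bank(8, duration_s=10.0, seed=0)
examples = build_training_set(bank, PRETRAIN, seed=0, training=True)

for i, ex in enumerate(examples):
    heart = ex.references.heart
    lung_db = 10 * np.log10(ex.references.lung.power() / heart.power())
    resid = ex.mixture.samples - ex.references.heart.samples \
        - ex.references.lung.samples
    if ex.noise_reference is not None:
        resid = resid - ex.noise_reference.samples
    print(f"ex {i}: partition={ex.partition:20s} "
          f"noise={str(ex.noise_class):22s} "
          f"noise_db={('%+.1f' % ex.noise_rel_db) if ex.noise_rel_db is not None else '  --'} "
          f"lung_db={lung_db:+.1f} (drawn {ex.lung_rel_db:+.1f}) "
          f"|mix - sum(refs)| = {np.max(np.abs(resid)):.1e}")

# Every drawn dB offset is realised exactly, noise levels stay inside
# the pretraining range (-20..0 dB), stethoscope movement never
# appears in a training build, and the mixture is the exact sum of its
# stored references - the targets are what the network can recover.
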