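"""SI-SDR training: objective, optimiser wiring, curriculum, plateau
learning-rate schedule, gradient clipping.

The objective maximises the scale-invariant signal-to-distortion ratio
between each estimate and its target,

    alpha   = <s_est, s_target> / ||s_target||^2
    e_noise = alpha * s_target - s_est
    SI-SDR  = 10 log10(||alpha * s_target||^2 / ||e_noise||^2),

averaged over the two sources; the loss is its negation.  Per-source
SI-SDR is clamped to +/-60 dB for numerical stability (an exact match
would otherwise be +inf).

Training runs the two-phase noise curriculum (pretraining with noise
at -20..0 dB relative power, fine-tuning at -10..10 dB), drawing a
fresh random 8-s crop of every example each epoch, with AdamW +
AMSGrad (weight decay 0.1), global gradient clipping at L2 norm 5 and
a plateau scheduler that halves the learning rate when validation
SI-SDR has not improved for 4 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .mixing import (FINETUNE, PRETRAIN, CurriculumPhase, MixtureExample,
                     random_crop)
from .model import Separator
from .tensor import DTYPE, Tensor

SI_SDR_CLAMP_DB = 60.0


@dataclass
class TrainConfig:
    epochs: int = 40
    batch_size: int = 16
    lr_init: float = 1e-4
    lr_factor: float = 0.5
    lr_patience: int = 4
    weight_decay: float = 0.1
    grad_clip_l2: float = 5.0
    crop_seconds: float = 8.0
    pretrain_epochs: int = 30  # remainder of `epochs` is the fine-tune phase
    phases: tuple[CurriculumPhase, ...] = (PRETRAIN, FINETUNE)
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lr_factor < 1.0):
            raise ValueError("lr_factor must be in (0, 1)")
        for name in ("epochs", "batch_size", "lr_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("lr_init", "weight_decay", "grad_clip_l2", "crop_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochRecord:
    epoch: int
    phase: str
    train_loss_db: float
    val_si_sdr_heart_db: float
    val_si_sdr_lung_db: float
    learning_rate: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def losses(self) -> list[float]:
        return [r.train_loss_db for r in self.records]


# ----------------------------------------------------------------------
# Objective
# ----------------------------------------------------------------------

def si_sdr_batch(estimates: Tensor, targets: np.ndarray) -> Tensor:
    """Per-pair clamped SI-SDR in dB for (..., T) stacks; differentiable."""
    t = np.asarray(targets, dtype=DTYPE)
    if t.shape != estimates.shape:
        raise ValueError(f"shape mismatch: estimates {estimates.shape} vs "
                         f"targets {t.shape}")
    t_energy = np.sum(t ** 2, axis=-1, keepdims=True)
    if np.any(t_energy == 0.0):
        raise ValueError("zero target in SI-SDR")
    tt = Tensor(t)
    alpha = (estimates * tt).sum(axis=-1, keepdims=True) * (1.0 / t_energy)
    proj = alpha * tt
    err = proj - estimates
    num = (proj * proj).sum(axis=-1) + 1e-30
    den = (err * err).sum(axis=-1) + 1e-30
    ratio_db = (num.log() - den.log()) * (10.0 / np.log(10.0))
    return ratio_db.clip(-SI_SDR_CLAMP_DB, SI_SDR_CLAMP_DB)


def si_sdr_loss(estimates: Tensor, targets: np.ndarray) -> Tensor:
    """Negative mean SI-SDR over all (source, example) pairs; lower is better."""
    return -si_sdr_batch(estimates, targets).mean()


def clip_gradients(gradient: np.ndarray, max_l2: float) -> np.ndarray:
    """Rescale a gradient vector so its L2 norm is at most ``max_l2``."""
    gradient = np.asarray(gradient, dtype=np.float64)
    norm = float(np.sqrt(np.sum(gradient ** 2)))
    if norm > max_l2:
        return gradient * (max_l2 / norm)
    return gradient


def lr_schedule_step(current_lr: float, history: list[float],
                     factor: float = 0.5, patience: int = 4) -> float:
    """Plateau rule on a higher-is-better validation series.

    The learning rate is multiplied by ``factor`` when the most recent
    ``patience`` values all failed to exceed the running best reached
    before them.
    """
    if not (0.0 < factor < 1.0):
        raise ValueError("factor must be in (0, 1)")
    if len(history) <= patience:
        return current_lr
    best_before = max(history[:-patience])
    if max(history[-patience:]) <= best_before:
        return current_lr * factor
    return current_lr


class PlateauScheduler:
    """Stateful wrapper: halves lr after ``patience`` non-improving epochs."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 4):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> float:
        if metric > self.best:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr *= self.factor
                self.bad_epochs = 0
        return self.lr


# ----------------------------------------------------------------------
# Batching
# ----------------------------------------------------------------------

def _crop_batch(examples: list[MixtureExample], crop_s: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fresh random crops -> (mixtures (B,T), targets (B,2,T))."""
    mixes, targets = [], []
    for ex in examples:
        m, h, l = random_crop(
            [ex.mixture, ex.references.heart, ex.references.lung],
            crop_s, rng)
        mixes.append(m.samples)
        targets.append(np.stack([h.samples, l.samples]))
    return np.stack(mixes), np.stack(targets)


def validate(model: Separator, val_set: list[MixtureExample]
             ) -> dict[str, float]:
    """Full-length evaluation-mode SI-SDR; mean and median per source."""
    if not val_set:
        raise ValueError("empty validation set")
    vals = np.empty((len(val_set), 2))
    for i, ex in enumerate(val_set):
        est = model.forward(ex.mixture.samples[None, :]).data[0]
        targets = np.stack([ex.references.heart.samples,
                            ex.references.lung.samples])
        vals[i] = si_sdr_batch(Tensor(est), targets).data
    return {
        "mean_heart": float(vals[:, 0].mean()),
        "mean_lung": float(vals[:, 1].mean()),
        "median_heart": float(np.median(vals[:, 0])),
        "median_lung": float(np.median(vals[:, 1])),
        "mean": float(vals.mean()),
    }


def train_steps(model: Separator, mixtures: np.ndarray, targets: np.ndarray,
                steps: int, lr: float = 1e-4, weight_decay: float = 0.1,
                grad_clip_l2: float = 5.0) -> list[float]:
    """Repeatedly fit one fixed batch; returns the per-step loss (dB).

    Used by the single-batch overfit check: a healthy network/gradient
    pipeline drives the SI-SDR loss down by several dB in a few hundred
    steps.
    """
    params = model.parameters()
    opt = nn.AdamW(params, lr=lr, weight_decay=weight_decay)
    losses = []
    for _ in range(steps):
        opt.zero_grad()
        loss = si_sdr_loss(model.forward(mixtures), targets)
        loss.backward()
        nn.clip_grad_norm(params, grad_clip_l2)
        opt.step()
        losses.append(float(loss.data))
    return losses


def train(model: Separator,
          train_sets: dict[str, list[MixtureExample]],
          val_set: list[MixtureExample],
          config: TrainConfig = TrainConfig(),
          verbose: bool = False) -> tuple[Separator, TrainHistory]:
    """Run the two-phase curriculum and return the best-validation model.

    ``train_sets`` maps phase name -> mixtures built for that phase
    (e.g. via :func:`neosep.mixing.build_training_set` with PRETRAIN
    and FINETUNE).  Epochs 1..pretrain_epochs use the first phase, the
    rest the second; phases absent from ``train_sets`` are skipped.
    Fully reproducible for a fixed ``config.seed``.
    """
    for name, exs in train_sets.items():
        if not exs:
            raise ValueError(f"empty training set for phase {name!r}")
    if not val_set:
        raise ValueError("empty validation set")

    params = model.parameters()
    opt = nn.AdamW(params, lr=config.lr_init, betas=config.betas,
                   weight_decay=config.weight_decay)
    sched = PlateauScheduler(config.lr_init, config.lr_factor,
                             config.lr_patience)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7E)))
    history = TrainHistory()
    best_metric = -np.inf
    best_state = model.state_dict()

    phase_of_epoch = []
    for e in range(config.epochs):
        phase = (config.phases[0] if e < config.pretrain_epochs
                 or len(config.phases) == 1 else config.phases[1])
        phase_of_epoch.append(phase)

    for epoch, phase in enumerate(phase_of_epoch, start=1):
        examples = train_sets.get(phase.name)
        if examples is None:
            continue
        order = rng.permutation(len(examples))
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            batch = [examples[i] for i in order[lo:lo + config.batch_size]]
            mixes, targets = _crop_batch(batch, config.crop_seconds, rng)
            opt.zero_grad()
            loss = si_sdr_loss(model.forward(mixes), targets)
            loss.backward()
            nn.clip_grad_norm(params, config.grad_clip_l2)
            opt.lr = sched.lr
            opt.step()
            epoch_losses.append(float(loss.data))
        stats = validate(model, val_set)
        metric = 0.5 * (stats["mean_heart"] + stats["mean_lung"])
        if metric > best_metric:
            best_metric = metric
            best_state = model.state_dict()
        lr_now = sched.lr
        sched.step(metric)
        history.records.append(EpochRecord(
            epoch=epoch, phase=phase.name,
            train_loss_db=float(np.mean(epoch_losses)),
            val_si_sdr_heart_db=stats["mean_heart"],
            val_si_sdr_lung_db=stats["mean_lung"],
            learning_rate=lr_now))
        if verbose:
            print(f"epoch {epoch:3d} [{phase.name}] "
                  f"loss {history.records[-1].train_loss_db:7.2f} dB  "
                  f"val H {stats['mean_heart']:6.2f} "
                  f"L {stats['mean_lung']:6.2f}  lr {lr_now:.2e}")

    model.load_state_dict(best_state)
    return model, history
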