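"""Objective distortion measures for separation quality.

An estimated source is decomposed into four additive parts,

    s_est = s_target + e_interf + e_noise + e_artif,

by successive orthogonal projections: onto the span of the true
target, then onto the span of target plus the other true sources
(interference), then additionally onto the noise (perturbation), with
the unexplained remainder counted as algorithmic artifact.  The
projections here are time-invariant subspace projections (whole-signal
span, i.e. allowed distortion is a single gain); SDR is

    SDR = 10 log10( ||s_target||^2 / ||e_interf + e_noise + e_artif||^2 ),

and SI-SDR is the scale-invariant ratio computed from the optimal
scalar projection of the estimate onto the target.  Improvements
(SDRi, SI-SDRi) subtract the same metric evaluated with the
unprocessed mixture as the estimate.  All dB values are clamped to
+/-60.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioSignal
from .mixing import PARTITIONS

CLAMP_DB = 60.0


def _db(num: float, den: float) -> float:
    """Clamped 10*log10(num/den)."""
    if num <= 0.0:
        return -CLAMP_DB
    if den <= 0.0:
        return CLAMP_DB
    return float(np.clip(10.0 * np.log10(num / den), -CLAMP_DB, CLAMP_DB))


def _vec(x) -> np.ndarray:
    if isinstance(x, AudioSignal):
        return x.samples
    return np.asarray(x, dtype=np.float64)


def si_sdr(estimate, target) -> float:
    """Scale-invariant SDR in dB (clamped to +/-60)."""
    e, t = _vec(estimate), _vec(target)
    if e.shape != t.shape:
        raise ValueError("estimate and target must have equal length")
    t_energy = float(t @ t)
    if t_energy == 0.0:
        raise ValueError("zero target in SI-SDR")
    alpha = float(e @ t) / t_energy
    proj = alpha * t
    err = proj - e
    return _db(float(proj @ proj), float(err @ err))


@dataclass(frozen=True)
class Decomposition:
    """The four additive components of an estimated source."""

    s_target_component: np.ndarray
    e_interf: np.ndarray
    e_noise: np.ndarray
    e_artif: np.ndarray

    def total_error(self) -> np.ndarray:
        return self.e_interf + self.e_noise + self.e_artif

    def reassembled(self) -> np.ndarray:
        return self.s_target_component + self.total_error()


def _project(estimate: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Orthogonal projection of ``estimate`` onto span(basis) (pseudo-inverse)."""
    A = np.stack(basis, axis=1)                       # (T, k)
    coef, *_ = np.linalg.lstsq(A, estimate, rcond=None)
    return A @ coef


def bss_decompose(estimate, target, other_sources=(), noise=None
                  ) -> Decomposition:
    """Decompose an estimate into target/interference/noise/artifact parts."""
    e = _vec(estimate)
    t = _vec(target)
    others = [_vec(o) for o in other_sources]
    n = _vec(noise) if noise is not None else None
    for v in [t, *others] + ([n] if n is not None else []):
        if v.shape != e.shape:
            raise ValueError("all signals must have equal length")
    if float(t @ t) == 0.0:
        raise ValueError("zero target in decomposition")

    p_t = _project(e, [t])
    p_ts = _project(e, [t, *others]) if others else p_t
    p_tsn = _project(e, [t, *others, n]) if n is not None else p_ts
    return Decomposition(
        s_target_component=p_t,
        e_interf=p_ts - p_t,
        e_noise=p_tsn - p_ts,
        e_artif=e - p_tsn,
    )


def sdr(decomposition: Decomposition) -> float:
    """SDR in dB of a decomposition (clamped to +/-60)."""
    s = decomposition.s_target_component
    err = decomposition.total_error()
    return _db(float(s @ s), float(err @ err))


def sdr_from_signals(estimate, target, other_sources=(), noise=None) -> float:
    return sdr(bss_decompose(estimate, target, other_sources, noise))


def improvement(estimate_db: float, baseline_db: float) -> float:
    """Metric improvement over using the unprocessed mixture as estimate."""
    return estimate_db - baseline_db


@dataclass(frozen=True)
class EvalResult:
    example_id: str
    partition: str
    source: str            # "heart" or "lung"
    sdr_db: float
    si_sdr_db: float
    sdri_db: float
    si_sdri_db: float


def evaluate_example(example, estimates, example_id: str = "0"
                     ) -> list[EvalResult]:
    """Score one mixture: per-source SDR/SI-SDR and their improvements.

    ``example`` is a :class:`neosep.mixing.MixtureExample`;
    ``estimates`` a :class:`neosep.synthesis.SourceSet` from the model.
    """
    mix = example.mixture
    refs = {"heart": example.references.heart, "lung": example.references.lung}
    ests = {"heart": estimates.heart, "lung": estimates.lung}
    noise = example.noise_reference
    out = []
    for src in ("heart", "lung"):
        other = [refs["lung" if src == "heart" else "heart"]]
        est_sdr = sdr_from_signals(ests[src], refs[src], other, noise)
        base_sdr = sdr_from_signals(mix, refs[src], other, noise)
        est_si = si_sdr(ests[src], refs[src])
        base_si = si_sdr(mix, refs[src])
        out.append(EvalResult(
            example_id=example_id, partition=example.partition, source=src,
            sdr_db=est_sdr, si_sdr_db=est_si,
            sdri_db=improvement(est_sdr, base_sdr),
            si_sdri_db=improvement(est_si, base_si)))
    return out


def evaluate_model(model, examples) -> list[EvalResult]:
    """Run the separator over labeled mixtures and score every source."""
    results = []
    for i, ex in enumerate(examples):
        est = model.separate(ex.mixture)
        results.extend(evaluate_example(ex, est, example_id=f"{i:04d}"))
    return results


def results_frame(results: list[EvalResult]) -> pd.DataFrame:
    if not results:
        raise ValueError("no results to tabulate")
    return pd.DataFrame([r.__dict__ for r in results])


def summarize(results: list[EvalResult]) -> pd.DataFrame:
    """Medians and quartiles by partition and source.

    Quartiles use linear interpolation.  Returns one row per
    (partition, source) with columns for SDRi and SI-SDRi medians and
    interquartile endpoints, plus the example count.
    """
    df = results_frame(results)
    rows = []
    for (part, src), g in df.groupby(["partition", "source"], sort=False):
        row = {"partition": part, "source": src, "n": len(g)}
        for col in ("sdri_db", "si_sdri_db"):
            row[f"median_{col}"] = float(g[col].median())
            row[f"q1_{col}"] = float(g[col].quantile(0.25))
            row[f"q3_{col}"] = float(g[col].quantile(0.75))
        rows.append(row)
    order = {p: i for i, p in enumerate(PARTITIONS)}
    out = pd.DataFrame(rows)
    out["_p"] = out["partition"].map(order)
    return (out.sort_values(["_p", "source"]).drop(columns="_p")
            .reset_index(drop=True))
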