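"""Rule-based emulation of visual tonic / phasic / "any" RWA scoring.

Human scorers rate chin-EMG activity during REM against the local background
tone: *phasic* activity is short bursts (0.1-5 s) at about twice the
background amplitude, scored on 3-s mini-epochs; *tonic* activity is
sustained elevated tone covering more than half of a 30-s epoch; *any*
combines both on mini-epochs.  This module applies those numeric rules to
the amplitude-curve envelope so the three percentage parameters can be
computed on synthetic or real signals without a human in the loop.  It is
an *emulation* of the visual standard, not a reproduction of any individual
scorer; every threshold is exposed in :class:`VisualConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_psg import EmgSignal, Hypnogram
from .rwa_core import (
    AmplitudeCurve,
    DetectionConfig,
    estimate_baseline,
    preprocess,
    _runs,
)

__all__ = [
    "VisualConfig",
    "VisualScores",
    "score_phasic",
    "score_tonic",
    "score_any",
    "score_visual",
]


@dataclass
class VisualConfig:
    """Thresholds of the emulated visual scoring rules."""

    phasic_min_s: float = 0.1
    phasic_max_s: float = 5.0
    amp_ratio: float = 2.0            # multiple of local background amplitude
    tonic_epoch_fraction: float = 0.5  # strict ">" of the 30-s epoch
    background_window_s: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.phasic_min_s < self.phasic_max_s:
            raise ValueError("need 0 < phasic_min_s < phasic_max_s")
        if not self.amp_ratio > 1:
            raise ValueError("amp_ratio must exceed 1")
        if not 0 < self.tonic_epoch_fraction < 1:
            raise ValueError("tonic_epoch_fraction must be in (0, 1)")


@dataclass
class VisualScores:
    """The three visual RWA percentages over REM sleep."""

    tonic_pct: float
    phasic_pct: float
    any_pct: float


def _elevated_runs(sig: EmgSignal, vcfg: VisualConfig):
    """Intervals where the EMG envelope exceeds amp_ratio x background tone.

    The envelope here is a sliding-window RMS rather than the detector's
    peak-to-peak curve: a human comparing burst amplitude to background tone
    integrates over the burst, and an RMS is robust to the single extreme
    samples that would otherwise hold a max-based envelope above threshold
    for a whole window.  The background is the exclusion-aware running
    *median* RMS (same causal machinery as the detector baseline, exclusion
    ratio ``amp_ratio``), so sustained tone does not inflate its own
    reference.  Runs shorter than ``phasic_min_s`` are dropped as noise.
    """
    dcfg = DetectionConfig(baseline_window_s=vcfg.background_window_s,
                           baseline_percentile=50.0)
    filtered = preprocess(sig, dcfg)
    rms = np.sqrt(ndimage.uniform_filter1d(
        filtered.samples ** 2, dcfg.window_samples, mode="nearest"))
    env = AmplitudeCurve(values=rms, rate=sig.rate, start_time=sig.start_time)
    bg = estimate_baseline(env, dcfg, exclude_factor=vcfg.amp_ratio)
    mask = env.values > vcfg.amp_ratio * bg.values
    runs = [(i / env.rate, j / env.rate) for i, j in _runs(mask)]
    return [(a, b) for a, b in runs if b - a >= vcfg.phasic_min_s - 1e-12]


def _rem_minis(hyp: Hypnogram, mini_s: float = 3.0):
    per = int(round(hyp.epoch_len / mini_s))
    out = []
    for k, stage in enumerate(hyp.stages):
        if stage == "REM":
            out.extend((k * hyp.epoch_len + j * mini_s,
                        k * hyp.epoch_len + (j + 1) * mini_s)
                       for j in range(per))
    if not out:
        raise ValueError("no REM sleep in recording")
    return out


def _overlaps(interval, runs) -> bool:
    a, b = interval
    return any(min(b, e) - max(a, s) > 0 for s, e in runs)


def score_visual(sig: EmgSignal, hyp: Hypnogram,
                 vcfg: VisualConfig | None = None,
                 mini_epoch_s: float = 3.0) -> VisualScores:
    """Compute tonic, phasic and any percentages in one envelope pass.

    Phasic and any are scored on REM 3-s mini-epochs, tonic on REM 30-s
    epochs (>50 % of the epoch covered by elevated tone).  By construction
    every phasic-positive mini-epoch is also any-positive, so
    ``any_pct >= phasic_pct``.
    """
    vcfg = vcfg or VisualConfig()
    runs = _elevated_runs(sig, vcfg)
    phasic_runs = [r for r in runs
                   if r[1] - r[0] <= vcfg.phasic_max_s + 1e-12]
    long_runs = [r for r in runs if r[1] - r[0] > vcfg.phasic_max_s + 1e-12]

    minis = _rem_minis(hyp, mini_epoch_s)
    n_phasic = sum(_overlaps(m, phasic_runs) for m in minis)
    n_any = sum(
        _overlaps(m, phasic_runs) or _overlaps(m, long_runs) for m in minis
    )

    rem_epochs = hyp.epochs_of("REM")
    n_tonic = 0
    for k in rem_epochs:
        t0, t1 = k * hyp.epoch_len, (k + 1) * hyp.epoch_len
        covered = sum(max(0.0, min(t1, e) - max(t0, s)) for s, e in runs)
        if covered > vcfg.tonic_epoch_fraction * hyp.epoch_len:
            n_tonic += 1

    return VisualScores(
        tonic_pct=100.0 * n_tonic / len(rem_epochs),
        phasic_pct=100.0 * n_phasic / len(minis),
        any_pct=100.0 * n_any / len(minis),
    )


def score_phasic(sig: EmgSignal, hyp: Hypnogram,
                 vcfg: VisualConfig | None = None) -> float:
    """% of REM 3-s mini-epochs containing a 0.1-5 s supra-background burst."""
    return score_visual(sig, hyp, vcfg).phasic_pct


def score_tonic(sig: EmgSignal, hyp: Hypnogram,
                vcfg: VisualConfig | None = None) -> float:
    """% of REM 30-s epochs with elevated tone covering more than half."""
    return score_visual(sig, hyp, vcfg).tonic_pct


def score_any(sig: EmgSignal, hyp: Hypnogram,
              vcfg: VisualConfig | None = None) -> float:
    """% of REM mini-epochs with phasic- or tonic-qualifying activity."""
    return score_visual(sig, hyp, vcfg).any_pct
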