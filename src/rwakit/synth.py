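"""Synthetic chin-EMG recordings and cohorts with planted ground truth.

The signal generator emulates the three activity classes the RWA detector
targets: a band-limited Gaussian *atonia floor* (quiet REM chin tone),
short *phasic bursts* (0.1-5 s) and sustained *tonic segments*.  Bursts and
tone multiply the local noise envelope rather than adding spikes, which is
closer to surface-EMG physiology and keeps a ratio-based detector in its
design regime.  An occupancy-planting mode places bursts so that an exact,
known number of REM mini-epochs is decisively positive, giving a planted
ground truth for closure tests.

The cohort generator draws subject tables (RWA parameters, AHI, PLMI,
dopamine-transporter imaging values) from truncated-normal marginals whose
*post-truncation* means match the requested group means, optionally with a
Gaussian-copula correlation structure.  Defaults reproduce the group
composition of the validation study's clinical table (11 healthy controls,
24 PD without RBD, 45 iRBD, 46 PD with RBD).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps, stats as spstats

from .io_psg import EmgSignal, Hypnogram, write_edf, write_hypnogram

__all__ = [
    "SynthSignalSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_signal",
    "generate_cohort",
    "default_cohort_spec",
    "emit_recording",
    "DEFAULT_HYPNOGRAM_BLOCKS",
]

#: One sleep cycle: W 10 min, S1 5, S2 30, S3 20, REM 20.
DEFAULT_HYPNOGRAM_BLOCKS = (
    ("W", 600.0), ("S1", 300.0), ("S2", 1800.0), ("S3", 1200.0),
    ("REM", 1200.0),
)


@dataclass
class SynthSignalSpec:
    """Recipe for one synthetic chin-EMG recording (all times in seconds)."""

    rate: float = 256.0
    atonia_rms_uv: float = 2.0
    burst_rate_per_min: float = 0.0
    burst_amp_ratio: float = 8.0
    burst_dur_range_s: tuple = (0.1, 5.0)
    burst_min_gap_s: float = 1.0
    tonic_segments: tuple = ()            # (start, end, amp_ratio) triples
    target_occupancy: float | None = None
    occupancy_burst_s: float = 2.0        # planted burst length per mini
    hypnogram_spec: tuple = DEFAULT_HYPNOGRAM_BLOCKS
    epoch_len: float = 30.0
    mini_epoch_s: float = 3.0
    ramp_s: float = 0.05
    band_hz: tuple = (10.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rate > 0 or not self.atonia_rms_uv > 0:
            raise ValueError("rate and atonia_rms_uv must be positive")
        lo, hi = self.burst_dur_range_s
        if not 0 < lo <= hi:
            raise ValueError("burst_dur_range_s must be 0 < lo <= hi")
        if self.target_occupancy is not None:
            if not 0 <= self.target_occupancy <= 1:
                raise ValueError("target_occupancy must be in [0, 1]")
            half = self.mini_epoch_s / 2
            if not half < self.occupancy_burst_s <= self.mini_epoch_s:
                raise ValueError(
                    "occupancy_burst_s must exceed half a mini-epoch (so the "
                    "planted mini is unambiguously positive) and fit inside it"
                )
        for stage, sec in self.hypnogram_spec:
            if sec <= 0:
                raise ValueError(f"non-positive block duration for {stage}")


@dataclass
class GroundTruth:
    """Planted activity intervals and the planned positive REM mini-epochs."""

    events: list          # (start_s, end_s, kind) with kind phasic|tonic
    positive_minis: list  # ordinals among the REM mini-epoch sequence

    def to_dict(self) -> dict:
        return {"events": [list(e) for e in self.events],
                "positive_minis": list(self.positive_minis)}


def _build_hypnogram(spec: SynthSignalSpec) -> Hypnogram:
    stages: list = []
    for stage, sec in spec.hypnogram_spec:
        n = int(round(sec / spec.epoch_len))
        if n < 1:
            raise ValueError(f"block {stage} shorter than one epoch")
        stages.extend([stage] * n)
    return Hypnogram(stages=tuple(stages), epoch_len=spec.epoch_len)


def _rem_mini_starts(hyp: Hypnogram, mini_s: float) -> np.ndarray:
    per = int(round(hyp.epoch_len / mini_s))
    starts = []
    for k, stage in enumerate(hyp.stages):
        if stage == "REM":
            starts.extend(k * hyp.epoch_len + j * mini_s for j in range(per))
    return np.asarray(starts)


def _atonia_noise(n: int, rate: float, rms: float, band: tuple,
                  rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    nyq = rate / 2.0
    lo, hi = band[0] / nyq, min(band[1], 0.9 * nyq) / nyq
    sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y * (rms / np.std(y))


def _apply_interval(env: np.ndarray, rate: float, start: float, end: float,
                    ratio: float, ramp_s: float) -> None:
    i0, i1 = int(round(start * rate)), int(round(end * rate))
    i0, i1 = max(i0, 0), min(i1, env.size)
    if i1 <= i0:
        return
    n = i1 - i0
    w = np.ones(n)
    nr = min(int(round(ramp_s * rate)), n // 2)
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        w[:nr] = ramp
        w[-nr:] = ramp[::-1]
    env[i0:i1] = np.maximum(env[i0:i1], 1.0 + (ratio - 1.0) * w)


def generate_signal(spec: SynthSignalSpec):
    """Synthesise ``(EmgSignal, Hypnogram, GroundTruth)`` from a spec.

    Identical spec and seed give bit-identical output.  With
    ``target_occupancy`` set, ``round(target * n_rem_minis)`` REM
    mini-epochs are selected and a ``occupancy_burst_s``-long burst is
    centred in each, leaving atonia gaps between neighbouring planted
    minis; no other activity is planted.
    """
    rng = np.random.default_rng(spec.seed)
    hyp = _build_hypnogram(spec)
    duration = hyp.duration_s
    n = int(round(duration * spec.rate))
    noise = _atonia_noise(n, spec.rate, spec.atonia_rms_uv, spec.band_hz, rng)
    env = np.ones(n)
    events: list = []

    rem_starts = _rem_mini_starts(hyp, spec.mini_epoch_s)
    planned: list = []

    if spec.target_occupancy is not None:
        n_rem = rem_starts.size
        k = int(round(spec.target_occupancy * n_rem))
        if k > n_rem or (spec.target_occupancy > 0 and n_rem == 0):
            raise ValueError(
                f"cannot realise occupancy {spec.target_occupancy}: "
                f"recording has {n_rem} REM mini-epochs"
            )
        chosen = np.sort(rng.choice(n_rem, size=k, replace=False))
        pad = (spec.mini_epoch_s - spec.occupancy_burst_s) / 2.0
        for idx in chosen:
            a = rem_starts[idx] + pad
            b = a + spec.occupancy_burst_s
            kind = "phasic" if spec.occupancy_burst_s <= 5.0 else "tonic"
            events.append((float(a), float(b), kind))
        planned = [int(i) for i in chosen]
    elif spec.burst_rate_per_min > 0:
        lam = spec.burst_rate_per_min * duration / 60.0
        n_bursts = rng.poisson(lam)
        placed: list = []
        for _ in range(n_bursts):
            dur = rng.uniform(*spec.burst_dur_range_s)
            for _attempt in range(200):
                a = rng.uniform(0.0, max(duration - dur, 1e-9))
                b = a + dur
                if all(a - e >= spec.burst_min_gap_s or
                       s - b >= spec.burst_min_gap_s for s, e in placed):
                    placed.append((a, b))
                    events.append((float(a), float(b),
                                   "phasic" if dur <= 5.0 else "tonic"))
                    break
        events.sort()

    for seg in spec.tonic_segments:
        a, b, ratio = seg
        if not 0 <= a < b <= duration:
            raise ValueError(f"tonic segment {seg} outside recording span")
        events.append((float(a), float(b), "tonic"))
    events.sort()

    for a, b, kind in events:
        ratio = spec.burst_amp_ratio
        for seg in spec.tonic_segments:
            if abs(seg[0] - a) < 1e-9 and abs(seg[1] - b) < 1e-9:
                ratio = seg[2]
        _apply_interval(env, spec.rate, a, b, ratio, spec.ramp_s)

    if spec.target_occupancy is None:
        planned = _planned_positive_minis(events, rem_starts, spec.mini_epoch_s)

    sig = EmgSignal(samples=noise * env, rate=spec.rate, label="Chin1-Chin2")
    return sig, hyp, GroundTruth(events=events, positive_minis=planned)


def _planned_positive_minis(events: Sequence, rem_starts: np.ndarray,
                            mini_s: float) -> list:
    out = []
    for i, t0 in enumerate(rem_starts):
        t1 = t0 + mini_s
        cover = sum(max(0.0, min(b, t1) - max(a, t0)) for a, b, _ in events)
        if cover > mini_s / 2:
            out.append(i)
    return out


def emit_recording(out_dir, spec: SynthSignalSpec) -> dict:
    """Write a synthetic recording as EDF + hypnogram CSV + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig, hyp, truth = generate_signal(spec)
    paths = {
        "edf": out_dir / "recording.edf",
        "hypnogram": out_dir / "hypnogram.csv",
        "truth": out_dir / "truth.json",
    }
    write_edf(paths["edf"], sig)
    write_hypnogram(paths["hypnogram"], hyp)
    with open(paths["truth"], "w") as fh:
        payload = {"spec": _spec_dict(spec), "ground_truth": truth.to_dict()}
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def _spec_dict(spec: SynthSignalSpec) -> dict:
    d = asdict(spec)
    d["hypnogram_spec"] = [list(b) for b in spec.hypnogram_spec]
    d["tonic_segments"] = [list(s) for s in spec.tonic_segments]
    d["burst_dur_range_s"] = list(spec.burst_dur_range_s)
    d["band_hz"] = list(spec.band_hz)
    return d


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Valid range of each subject-table variable (truncation bounds).
VARIABLE_RANGES: dict = {
    "age": (18.0, 100.0),
    "phasic_pct": (0.0, 100.0),
    "tonic_pct": (0.0, 100.0),
    "any_pct": (0.0, 100.0),
    "auto_rwa": (0.0, 1.0),
    "ahi": (0.0, math.inf),
    "plmi": (0.0, math.inf),
    "caudate_sbr": (0.0, math.inf),
    "putamen_sbr": (0.0, math.inf),
    "caudate_z": (-math.inf, math.inf),
    "putamen_z": (-math.inf, math.inf),
}

#: Group means +/- SD of the validation cohort's clinical table.
_TABLE_GROUPS: dict = {
    "HC": dict(n=11, male_frac=0.4545, age=(67.27, 11.41),
               phasic_pct=(3.28, 3.41), tonic_pct=(1.07, 1.74),
               any_pct=(4.90, 4.77), auto_rwa=(0.13, 0.20),
               ahi=(4.87, 6.80), plmi=(20.61, 40.86)),
    "PDnoRBD": dict(n=24, male_frac=0.5416, age=(66.67, 9.47),
                    phasic_pct=(5.77, 3.94), tonic_pct=(2.73, 2.59),
                    any_pct=(7.78, 4.92), auto_rwa=(0.11, 0.07),
                    ahi=(12.84, 18.61), plmi=(5.75, 9.94),
                    caudate_sbr=(2.55, 1.01), putamen_sbr=(1.53, 0.65),
                    caudate_z=(-1.69, 0.33), putamen_z=(-1.92, 0.36)),
    "iRBD": dict(n=45, male_frac=0.80, age=(68.51, 7.79),
                 phasic_pct=(45.38, 23.03), tonic_pct=(38.35, 25.40),
                 any_pct=(59.61, 23.48), auto_rwa=(0.28, 0.18),
                 ahi=(5.72, 7.84), plmi=(25.22, 37.84),
                 caudate_sbr=(3.52, 1.10), putamen_sbr=(2.85, 0.95),
                 caudate_z=(-1.24, 0.42), putamen_z=(-1.29, 0.28)),
    "PD_RBD": dict(n=46, male_frac=0.6304, age=(72.46, 6.25),
                   phasic_pct=(29.77, 20.22), tonic_pct=(45.44, 29.97),
                   any_pct=(57.35, 24.81), auto_rwa=(0.39, 0.21),
                   ahi=(16.41, 18.12), plmi=(24.24, 27.55),
                   caudate_sbr=(2.24, 0.62), putamen_sbr=(1.36, 0.51),
                   caudate_z=(-1.69, 0.30), putamen_z=(-1.85, 0.30)),
}

RBD_GROUPS = ("iRBD", "PD_RBD")


@dataclass
class CohortSpec:
    """Per-group marginal means/SDs plus an optional correlation request.

    ``groups`` maps a group label to ``{"n": ..., "male_frac": ...,
    var: (mean, sd), ...}``.  ``correlations`` maps variable pairs to a
    Pearson correlation imposed on the underlying Gaussian copula (default
    independent).
    """

    groups: dict = field(default_factory=lambda: _copy_groups())
    correlations: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, params in self.groups.items():
            if params.get("n", 0) < 2:
                raise ValueError(f"group {g}: need n >= 2")
            for var, ms in params.items():
                if var in ("n", "male_frac"):
                    continue
                mean, sd = ms
                if sd < 0:
                    raise ValueError(f"group {g}, {var}: SD must be >= 0")
                lo, hi = VARIABLE_RANGES.get(var, (-math.inf, math.inf))
                if not lo <= mean <= hi:
                    raise ValueError(
                        f"group {g}, {var}: mean {mean} outside [{lo}, {hi}]"
                    )
        for pair, rho in self.correlations.items():
            if not -1 < rho < 1:
                raise ValueError(f"correlation for {pair} must be in (-1, 1)")


def _copy_groups() -> dict:
    return {g: dict(p) for g, p in _TABLE_GROUPS.items()}


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The validation cohort's group structure as a generator spec."""
    return CohortSpec(groups=_copy_groups(), seed=seed)


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Underlying normal location whose [lo, hi]-truncated mean hits target."""
    if sd == 0:
        return target_mean

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return spstats.truncnorm.mean(a, b, loc=loc, scale=sd)

    span = 10 * sd
    try:
        return optimize.brentq(lambda L: trunc_mean(L) - target_mean,
                               target_mean - span, target_mean + span,
                               xtol=1e-10)
    except ValueError:
        # target at the very edge of the feasible range
        return target_mean


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a subject table (one row per subject) from a :class:`CohortSpec`.

    Marginals are truncated normals whose post-truncation mean equals the
    requested mean (the underlying location is solved for); the truncated SD
    is at most the requested SD.  Variables absent from a group's spec (for
    instance imaging in healthy controls) come out as NaN.
    """
    spec = spec or default_cohort_spec()
    rng = np.random.default_rng(spec.seed)
    all_vars = [v for v in VARIABLE_RANGES
                if any(v in p for p in spec.groups.values())]
    rows = []
    sid = 0
    for group, params in spec.groups.items():
        n = int(params["n"])
        gvars = [v for v in all_vars if v in params]
        R = np.eye(len(gvars))
        for (va, vb), rho in spec.correlations.items():
            if va in gvars and vb in gvars:
                i, j = gvars.index(va), gvars.index(vb)
                R[i, j] = R[j, i] = rho
        if np.linalg.eigvalsh(R).min() < -1e-9:
            raise ValueError("requested correlation matrix is not PSD")
        z = rng.multivariate_normal(np.zeros(len(gvars)), R, size=n,
                                    method="cholesky")
        u = spstats.norm.cdf(z)
        data = {}
        for j, var in enumerate(gvars):
            mean, sd = params[var]
            lo, hi = VARIABLE_RANGES.get(var, (-math.inf, math.inf))
            if sd == 0:
                data[var] = np.full(n, mean)
                continue
            loc = _truncnorm_loc(mean, sd, lo, hi)
            a, b = (lo - loc) / sd, (hi - loc) / sd
            data[var] = spstats.truncnorm.ppf(u[:, j], a, b, loc=loc, scale=sd)
        male = rng.random(n) < params.get("male_frac", 0.5)
        for i in range(n):
            sid += 1
            row = {"subject": f"S{sid:03d}", "group": group,
                   "sex": "M" if male[i] else "F",
                   "rbd": int(group in RBD_GROUPS)}
            for var in all_vars:
                row[var] = float(data[var][i]) if var in data else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
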