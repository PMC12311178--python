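"""Synthetic Lead-I-style ECG and left-ventricular-pressure (LVP) traces.

Every downstream stage of the heart-rate DSP chain is exercised on traces
produced here, so the generator is built around an *exact* beat clock: given
an instantaneous heart-rate profile r(t) (bpm), the k-th beat is placed at the
time where the integrated rate ``B(t) = (1/60) * integral_0^t r`` reaches k
(beat 0 at t = 0).  The profile is piecewise constant ("hold") or piecewise
linear, so the integral is piecewise linear/quadratic and beat times are
solved in closed form — no quadrature error.  Stepped profiles aligned to the
5-s analysis grid therefore yield analytically known per-window heart rates.

Morphology is deliberately simple: each beat is a raised-cosine R wave
(~80 ms) flanked by optional low-amplitude P and T bumps, which is QRS
dominance without 12-lead realism.  The LVP channel shares the same beat
clock; its pressure pulse is shaped so the mid-upstroke (50% level) falls
exactly on the beat time, giving a gold-standard edge clock.

Units are arbitrary (millivolt-scale ECG, mmHg-scale LVP); only timing
matters downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HRProfile",
    "NoiseConfig",
    "SampledTrace",
    "make_hr_profile",
    "synthesize_ecg",
    "synthesize_lvp",
    "write_trace_csv",
    "read_trace_csv",
]

_HR_MIN, _HR_MAX = 20.0, 300.0


@dataclass(frozen=True)
class HRProfile:
    """Instantaneous heart-rate profile defined by breakpoints.

    ``breakpoints`` is a sequence of (time s, HR bpm) with strictly increasing
    times; ``interpolation`` is ``"hold"`` (step) or ``"linear"`` (ramp).
    Beyond the last breakpoint the last value holds.
    """

    breakpoints: tuple[tuple[float, float], ...]
    interpolation: str = "hold"

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("HRProfile needs at least one breakpoint")
        if self.interpolation not in ("hold", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        times = [t for t, _ in self.breakpoints]
        for (t0, _), (t1, _) in zip(self.breakpoints, self.breakpoints[1:]):
            if t1 <= t0:
                raise ValueError(
                    f"breakpoint times must be strictly increasing: {t0} -> {t1}"
                )
        for t, hr in self.breakpoints:
            if not (_HR_MIN < hr < _HR_MAX):
                raise ValueError(f"HR {hr} bpm at t={t} outside ({_HR_MIN}, {_HR_MAX})")

    def rate(self, t):
        """Instantaneous HR (bpm) at time(s) ``t``; vectorized."""
        t = np.asarray(t, dtype=float)
        times = np.array([b[0] for b in self.breakpoints])
        vals = np.array([b[1] for b in self.breakpoints])
        if self.interpolation == "linear":
            return np.interp(t, times, vals)
        idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(vals) - 1)
        return vals[idx]

    def _knots(self, duration: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Piecewise-linear rate representation on [0, duration].

        Returns (knot times, rate at segment start, rate at segment end) for
        each segment; hold profiles become flat segments.
        """
        times = [b[0] for b in self.breakpoints]
        vals = [b[1] for b in self.breakpoints]
        if times[0] > 0:
            times = [0.0] + times
            vals = [vals[0]] + vals
        knots, r_lo, r_hi = [], [], []
        for i in range(len(times)):
            a = times[i]
            b = times[i + 1] if i + 1 < len(times) else duration
            if a >= duration:
                break
            b = min(b, duration)
            if b <= a:
                continue
            if self.interpolation == "linear" and i + 1 < len(times):
                ra, rb = vals[i], vals[i + 1]
                # partial segment: interpolate the end rate
                if b < times[i + 1]:
                    rb = vals[i] + (vals[i + 1] - vals[i]) * (b - a) / (times[i + 1] - a)
            else:
                ra = rb = vals[i]
            knots.append((a, b))
            r_lo.append(ra)
            r_hi.append(rb)
        return (np.array(knots), np.array(r_lo), np.array(r_hi))

    def beat_times(self, duration: float) -> np.ndarray:
        """Exact beat times on [0, duration): beat k where integrated rate = k."""
        segs, r_lo, r_hi = self._knots(duration)
        beats: list[float] = []
        b_acc = 0.0  # integrated beats at segment start
        for (a, b), ra, rb in zip(segs, r_lo, r_hi):
            length = b - a
            seg_beats = (ra + rb) / 2.0 * length / 60.0
            k0 = math.ceil(b_acc - 1e-9)
            k1 = b_acc + seg_beats
            k = k0
            while k < k1 - 1e-9:
                c = 60.0 * (k - b_acc)
                q = (rb - ra) / (2.0 * length)
                if abs(q) < 1e-12:
                    u = c / ra
                else:
                    u = (-ra + math.sqrt(ra * ra + 4.0 * q * c)) / (2.0 * q)
                t = a + u
                if t < duration - 1e-9:
                    if not beats or t > beats[-1] + 1e-9:
                        beats.append(t)
                k += 1
            b_acc += seg_beats
        return np.array(beats)

    def integrated_beats(self, duration: float) -> float:
        """Total integrated rate (beats) over [0, duration]."""
        segs, r_lo, r_hi = self._knots(duration)
        return float(sum((ra + rb) / 2 * (b - a) / 60 for (a, b), ra, rb in zip(segs, r_lo, r_hi)))


def make_hr_profile(
    segments: list[tuple[float, float]], interpolation: str = "hold"
) -> HRProfile:
    """Build an :class:`HRProfile` from (start time s, HR bpm) pairs."""
    return HRProfile(tuple((float(t), float(hr)) for t, hr in segments), interpolation)


@dataclass(frozen=True)
class NoiseConfig:
    """Additive confounders the 4–45 Hz bandpass is built to remove.

    Sinusoidal baseline wander + white sample noise + per-beat R-R jitter
    (fraction of the local R-R interval).  ``seed`` makes all draws
    reproducible; ECG and LVP noise streams are independent but share the
    jittered beat clock.
    """

    baseline_wander_amp: float = 0.1
    wander_freq: float = 0.3
    white_sigma: float = 0.05
    rr_jitter_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_wander_amp, self.wander_freq, self.white_sigma) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not (0 <= self.rr_jitter_sigma < 0.2):
            raise ValueError("rr_jitter_sigma must be in [0, 0.2)")


NOISELESS = NoiseConfig(0.0, 0.3, 0.0, 0.0, 0)


@dataclass
class SampledTrace:
    """Uniformly sampled biosignal.

    ``beat_times`` carries the generator's ground-truth beat clock (absent on
    traces read back from CSV); it is metadata for validation, not signal.
    """

    fs: float
    t0: float
    samples: np.ndarray
    kind: str = "ecg"
    beat_times: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


def _jittered_beats(
    profile: HRProfile, duration: float, noise: NoiseConfig
) -> np.ndarray:
    beats = profile.beat_times(duration)
    if noise.rr_jitter_sigma == 0 or len(beats) < 2:
        return beats
    rng = np.random.default_rng([int(noise.seed), 0])  # beat-clock stream
    rr = np.diff(beats)
    rr_local = np.concatenate([[rr[0]], rr])
    delta = rng.normal(0.0, noise.rr_jitter_sigma, len(beats)) * rr_local
    np.clip(delta, -0.4 * rr_local, 0.4 * rr_local, out=delta)
    out = np.sort(beats + delta)
    return out[(out >= 0) & (out < duration)]


def _raised_cos(u: np.ndarray, width: float) -> np.ndarray:
    """0.5*(1+cos(2*pi*u/width)) on |u| < width/2, else 0."""
    out = np.zeros_like(u)
    m = np.abs(u) < width / 2
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[m] / width))
    return out


def _check_synth_args(profile: HRProfile, duration: float, fs: float) -> None:
    if fs < 100:
        raise ValueError("fs must be >= 100 samples/s")
    if duration < 10:
        raise ValueError("duration must be >= 10 s")
    max_rr = 60.0 / min(hr for _, hr in profile.breakpoints)
    if duration < max_rr:
        raise ValueError("duration shorter than one beat period")


def synthesize_ecg(
    profile: HRProfile,
    duration: float,
    fs: float = 200.0,
    noise: NoiseConfig = NOISELESS,
    r_amp: float = 1.0,
    p_amp: float = 0.12,
    t_amp: float = 0.25,
    qrs_width: float = 0.08,
) -> SampledTrace:
    """Render a Lead-I-like ECG following ``profile``'s beat clock.

    R waves are raised cosines of height ``r_amp`` (>= 3x the P/T bumps by
    default); identical (profile, duration, fs, noise) give bit-identical
    traces.
    """
    _check_synth_args(profile, duration, fs)
    n = round(duration * fs)
    t = np.arange(n) / fs
    y = np.zeros(n)
    beats = _jittered_beats(profile, duration, noise)
    rr = np.diff(beats) if len(beats) > 1 else np.array([60.0 / profile.rate(0.0)])
    for i, tb in enumerate(beats):
        rr_prev = rr[i - 1] if i > 0 else rr[0]
        rr_next = rr[i] if i < len(rr) else rr[-1]
        i0 = max(0, int((tb - 0.45 * rr_prev) * fs))
        i1 = min(n, int((tb + 0.55 * rr_next) * fs) + 1)
        u = t[i0:i1]
        y[i0:i1] += r_amp * _raised_cos(u - tb, qrs_width)
        if p_amp > 0:
            y[i0:i1] += p_amp * _raised_cos(u - (tb - 0.22 * rr_prev), 0.09)
        if t_amp > 0:
            y[i0:i1] += t_amp * _raised_cos(u - (tb + 0.32 * rr_next), 0.16)
    if noise.baseline_wander_amp > 0 or noise.white_sigma > 0:
        rng = np.random.default_rng([int(noise.seed), 1])  # ECG noise stream
        phase = rng.uniform(0, 2 * np.pi)
        y += noise.baseline_wander_amp * np.sin(2 * np.pi * noise.wander_freq * t + phase)
        y += rng.normal(0.0, noise.white_sigma, n) if noise.white_sigma > 0 else 0.0
    return SampledTrace(fs=fs, t0=0.0, samples=y, kind="ecg", beat_times=beats)


def synthesize_lvp(
    profile: HRProfile,
    duration: float,
    fs: float = 200.0,
    noise: NoiseConfig = NOISELESS,
    base: float = 8.0,
    amp: float = 92.0,
    rise: float = 0.08,
) -> SampledTrace:
    """Render an LVP-like pressure trace sharing the ECG beat clock.

    Each beat produces one pressure pulse whose mid-upstroke (50% level)
    falls exactly on the beat time, so LVP rising edges and ECG R peaks agree
    to within a sample for matching (profile, seed).
    """
    _check_synth_args(profile, duration, fs)
    n = round(duration * fs)
    t = np.arange(n) / fs
    y = np.full(n, base)
    beats = _jittered_beats(profile, duration, noise)
    rr = np.diff(beats) if len(beats) > 1 else np.array([60.0 / profile.rate(0.0)])
    for i, tb in enumerate(beats):
        rr_next = rr[i] if i < len(rr) else rr[-1]
        fall = min(0.30, 0.5 * rr_next)
        a, b = tb - rise / 2, tb + rise / 2
        i0 = max(0, int(a * fs))
        i1 = min(n, int((b + fall) * fs) + 1)
        u = t[i0:i1]
        pulse = np.zeros_like(u)
        up = (u >= a) & (u < b)
        pulse[up] = 0.5 * (1.0 - np.cos(np.pi * (u[up] - a) / rise))
        dn = (u >= b) & (u < b + fall)
        pulse[dn] = 0.5 * (1.0 + np.cos(np.pi * (u[dn] - b) / fall))
        y[i0:i1] += amp * pulse
    if noise.white_sigma > 0:
        rng = np.random.default_rng([int(noise.seed), 2])  # LVP noise stream
        y += rng.normal(0.0, noise.white_sigma, n)
    return SampledTrace(fs=fs, t0=0.0, samples=y, kind="lvp", beat_times=beats)


def write_trace_csv(trace: SampledTrace, path) -> None:
    """Write ``time_s,value`` CSV; the sampling rate is recoverable from time."""
    pd.DataFrame({"time_s": trace.times, "value": trace.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_trace_csv(path, kind: str = "ecg") -> SampledTrace:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "value"]:
        raise ValueError(f"expected columns time_s,value, got {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace CSV needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return SampledTrace(fs=fs, t0=float(t[0]), samples=df["value"].to_numpy(), kind=kind)
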