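"""Heart-rate extraction chain of the central control unit (CCU).

Mirrors the real-time pipeline: a 24th-order high-pass FIR (4 Hz cutoff)
cascaded with a 48th-order low-pass FIR (45 Hz cutoff) at 200 samples/s,
adaptive R-peak detection, and a robust 5-s windowed median heart rate.
The filters are applied offline with explicit group-delay compensation
(both designs are linear-phase with an odd tap count, so centring the
convolution leaves peak times unshifted).

Also provides the baseline-HR rule (mean of the two most recent pre-stim
windows), the percent agreement metric

    average HR error = mean(|HR_sensed - HR_ref| / HR_ref) * 100%

and LVP rising-edge HR extraction, which serves as the gold-standard beat
clock in benchtop-style comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .ecg_synth import SampledTrace

__all__ = [
    "FilterSpec",
    "PeakSeries",
    "HRSeries",
    "design_fir_bandpass",
    "apply_filters",
    "detect_r_peaks",
    "hr_from_peaks_windowed",
    "compute_baseline_hr",
    "average_hr_error",
    "hr_from_lvp",
]


@dataclass(frozen=True)
class FilterSpec:
    """Cascaded FIR bandpass: high-pass then low-pass.

    ``hp_order``/``lp_order`` are filter orders (taps = order + 1);
    ``hp_cutoff`` is the centre of the high-pass transition band,
    ``lp_cutoff`` the -6 dB point of the windowed-sinc low-pass.
    """

    hp_order: int = 24
    hp_cutoff: float = 4.0
    lp_order: int = 48
    lp_cutoff: float = 45.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.hp_order <= 0 or self.lp_order <= 0:
            raise ValueError("filter orders must be positive")
        if self.hp_order % 2 or self.lp_order % 2:
            raise ValueError("filter orders must be even (linear phase, type I)")
        if not (0 < self.hp_cutoff < self.lp_cutoff):
            raise ValueError("need 0 < hp_cutoff < lp_cutoff")
        if self.lp_cutoff >= self.fs / 2:
            raise ValueError(
                f"lp_cutoff {self.lp_cutoff} Hz must be below Nyquist {self.fs / 2} Hz"
            )


def design_fir_bandpass(spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Design (high-pass taps, low-pass taps) for ``spec``.

    The high-pass is a spectrally inverted unit-DC least-squares low-pass
    (delta minus low-pass), which pins its DC gain to exactly zero while
    keeping the short 25-tap design flat (within ripple) from ~1.5x the
    cutoff upward; the transition band is cutoff +/- cutoff/2.  The
    low-pass is a Hamming-window sinc with unit DC gain and its -6 dB
    point at the cutoff.
    """
    half = spec.hp_cutoff / 2.0
    lp_proto = signal.firls(
        spec.hp_order + 1,
        [0.0, spec.hp_cutoff - half, spec.hp_cutoff + half, spec.fs / 2],
        [1.0, 1.0, 0.0, 0.0],
        fs=spec.fs,
    )
    lp_proto = lp_proto / lp_proto.sum()
    hp = -lp_proto
    hp[spec.hp_order // 2] += 1.0
    lp = signal.firwin(spec.lp_order + 1, spec.lp_cutoff, fs=spec.fs)
    return hp, lp


def apply_filters(trace: SampledTrace, spec: FilterSpec | None = None) -> SampledTrace:
    """Bandpass-filter a trace; output length equals input length.

    Each stage uses a centred convolution so the (taps-1)/2 group delay of
    the linear-phase FIRs is compensated and peak times are unbiased.
    """
    spec = spec or FilterSpec()
    if abs(trace.fs - spec.fs) > 1e-9:
        raise ValueError(f"trace fs {trace.fs} != filter fs {spec.fs}")
    hp, lp = design_fir_bandpass(spec)
    y = np.convolve(trace.samples, hp, mode="same")
    y = np.convolve(y, lp, mode="same")
    return SampledTrace(
        fs=trace.fs, t0=trace.t0, samples=y, kind="filtered", beat_times=trace.beat_times
    )


@dataclass
class PeakSeries:
    """Detected R-peak times (s, strictly increasing) and amplitudes."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if len(self.peak_times) > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")


def detect_r_peaks(
    filtered: SampledTrace,
    threshold_frac: float = 0.5,
    decay_tau: float = 2.0,
    refractory: float = 0.2,
) -> PeakSeries:
    """Adaptive R-peak detection on a bandpassed trace.

    Candidates are local maxima at least ``refractory`` apart; a candidate is
    accepted when it exceeds ``threshold_frac`` times a running peak-amplitude
    level that decays exponentially (time constant ``decay_tau``) since the
    last accepted peak — the minimal classical adaptive-threshold scheme.
    Peak times are refined to sub-sample precision by parabolic
    interpolation.  A flat or all-subthreshold trace yields an empty series.
    """
    x = filtered.samples
    fs = filtered.fs
    dist = max(1, int(round(refractory * fs)))
    idx, _ = signal.find_peaks(x, distance=dist)
    idx = idx[x[idx] > 0]
    if len(idx) == 0:
        return PeakSeries(np.array([]), np.array([]), filtered.duration)
    t_cand = filtered.t0 + idx / fs
    a_cand = x[idx]

    early = a_cand[t_cand <= t_cand[0] + 2.0]
    level = float(np.max(early))
    t_ref = t_cand[0]
    times, amps = [], []
    for tc, ac, ic in zip(t_cand, a_cand, idx):
        thr = threshold_frac * level * np.exp(-(tc - t_ref) / decay_tau)
        if ac < thr:
            continue
        if times and tc - times[-1] < refractory:
            continue
        # sub-sample refinement: parabola through the 3 samples around the max
        tp = tc
        if 0 < ic < len(x) - 1:
            denom = x[ic - 1] - 2 * x[ic] + x[ic + 1]
            if denom < 0:
                tp = tc + 0.5 * (x[ic - 1] - x[ic + 1]) / denom / fs
        times.append(tp)
        amps.append(ac)
        level = 0.75 * level + 0.25 * ac
        t_ref = tc
    return PeakSeries(np.array(times), np.array(amps), filtered.duration)


@dataclass
class HRSeries:
    """One HR value per 5-s window; missing windows are NaN."""

    window_starts: np.ndarray
    hr_bpm: np.ndarray
    window: float = 5.0

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if len(self.window_starts) != len(self.hr_bpm):
            raise ValueError("window_starts and hr_bpm lengths differ")

    def __len__(self) -> int:
        return len(self.hr_bpm)


def _windowed_median_hr(
    event_times: np.ndarray, duration: float, window: float, smooth: bool = False
) -> HRSeries:
    n_win = int(np.floor(duration / window + 1e-9))
    starts = np.arange(n_win) * window
    vals = np.full(n_win, np.nan)
    if len(event_times) >= 2:
        rr = np.diff(event_times)
        rates = 60.0 / rr
        if smooth and len(rates) >= 3:
            rates = pd.Series(rates).rolling(3, center=True, min_periods=1).median().to_numpy()
        ends = event_times[1:]
        widx = np.floor(ends / window).astype(int)
        for w in range(n_win):
            r = rates[widx == w]
            if len(r):
                hr = float(np.median(r))
                vals[w] = hr if 20.0 < hr < 300.0 else np.nan
    return HRSeries(starts, vals, window)


def hr_from_peaks_windowed(
    peaks: PeakSeries, window: float = 5.0, duration: float | None = None
) -> HRSeries:
    """5-s median HR: one value per window [k*w, (k+1)*w).

    Each R-R interval contributes 60/RR bpm to the window containing the
    interval's *ending* peak; a window's HR is the median of its intervals.
    Windows with no ending interval (or implausible HR) are NaN.
    """
    dur = duration if duration is not None else peaks.duration
    return _windowed_median_hr(peaks.peak_times, dur, window)


def compute_baseline_hr(history: HRSeries, stim_start: float) -> float:
    """Mean of the two most recent non-missing window HRs before ``stim_start``."""
    ends = history.window_starts + history.window
    ok = (ends <= stim_start + 1e-9) & np.isfinite(history.hr_bpm)
    vals = history.hr_bpm[ok]
    if len(vals) < 2:
        raise ValueError("insufficient baseline: need >= 2 windows before stimulation")
    return float(np.mean(vals[-2:]))


def average_hr_error(sensed: HRSeries, reference: HRSeries) -> float:
    """Percent agreement metric: mean(|sensed - ref| / ref) * 100 over common windows."""
    common = np.intersect1d(
        np.round(sensed.window_starts, 6), np.round(reference.window_starts, 6)
    )
    si = {round(t, 6): i for i, t in enumerate(sensed.window_starts)}
    ri = {round(t, 6): i for i, t in enumerate(reference.window_starts)}
    errs = []
    for t in common:
        s = sensed.hr_bpm[si[t]]
        r = reference.hr_bpm[ri[t]]
        if np.isfinite(s) and np.isfinite(r):
            if r <= 0:
                raise ValueError("reference HR must be positive")
            errs.append(abs(s - r) / r)
    if not errs:
        raise ValueError("no common non-missing windows to compare")
    return float(np.mean(errs) * 100.0)


def hr_from_lvp(lvp: SampledTrace, window: float = 5.0) -> HRSeries:
    """HR from the periodic separation of LVP rising edges.

    Edges are mid-level upward crossings of the lightly smoothed pressure
    (linear sub-sample interpolation, 200 ms refractory); edge-to-edge rates
    get a 3-point moving median before the usual 5-s windowing.  Traces with
    no pulses yield an all-missing series.
    """
    x = pd.Series(lvp.samples).rolling(5, center=True, min_periods=1).mean().to_numpy()
    lo, hi = np.percentile(x, [10, 90])
    n_win = int(np.floor(lvp.duration / window + 1e-9))
    if hi - lo < 1e-9:
        return HRSeries(np.arange(n_win) * window, np.full(n_win, np.nan), window)
    level = lo + 0.5 * (hi - lo)
    below = x[:-1] < level
    above = x[1:] >= level
    ci = np.nonzero(below & above)[0]
    edges = []
    for i in ci:
        frac = (level - x[i]) / (x[i + 1] - x[i])
        t = lvp.t0 + (i + frac) / lvp.fs
        if not edges or t - edges[-1] >= 0.2:
            edges.append(t)
    return _windowed_median_hr(np.array(edges), lvp.duration, window, smooth=True)
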