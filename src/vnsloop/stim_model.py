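"""Stimulation waveform semantics and the nerve-cuff electrical load.

Two halves:

* Pulse patterns.  A stimulation pulse of width PW is chopped into
  ``n_pulsons`` equal-width sub-pulses ("pulsons"); the pulse duty cycle is
  the summed pulson width divided by PW, and is the charge-injection proxy
  the closed-loop controller manipulates.  A traditional rectangular pulse
  is one pulson with zero spacing.

* Electrode-nerve load.  The cuff-nerve interface is modelled as a series
  access resistance R1 feeding R2 parallel C1 (or a constant phase element
  Q, alpha).  Complex impedance spectra (1 Hz - 10 kHz) can be simulated and
  fitted back by Levenberg-Marquardt with modulus (1/|Z|) weighting; onset
  currents and per-pulse charge follow from the same circuit's RC transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit

__all__ = [
    "StimParams",
    "PulsePattern",
    "CircuitParams",
    "ImpedanceSpectrum",
    "CircuitFit",
    "PAPER_GRADE_MEDIAN_CIRCUIT",
    "build_pulse_pattern",
    "circuit_impedance",
    "simulate_spectrum",
    "fit_circuit",
    "peak_current",
    "charge_per_pulse",
]

DUTY_LEVELS = (12.5, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class StimParams:
    """One stimulation setting.

    frequency in Hz (1-20), pulse_width in us (64-1024), duty_cycle in
    percent (12.5/25/50/100), pulson_voltage in V (2.6-3.7, the regulated
    on-chip level).  ``n_pulsons=1`` forces ``pulson_spacing=0`` (plain
    rectangular pulse).
    """

    frequency: float
    pulse_width: float
    duty_cycle: float
    n_pulsons: int = 1
    pulson_spacing: float = 0.0
    pulson_voltage: float = 3.3

    def __post_init__(self) -> None:
        if not (1.0 <= self.frequency <= 20.0):
            raise ValueError(f"frequency {self.frequency} Hz outside [1, 20]")
        if not (64.0 <= self.pulse_width <= 1024.0):
            raise ValueError(f"pulse width {self.pulse_width} us outside [64, 1024]")
        if not any(abs(self.duty_cycle - d) < 1e-9 for d in DUTY_LEVELS):
            raise ValueError(f"duty cycle {self.duty_cycle}% not in {DUTY_LEVELS}")
        if self.n_pulsons < 1:
            raise ValueError("n_pulsons must be >= 1")
        if self.n_pulsons == 1 and self.pulson_spacing != 0:
            raise ValueError("single-pulson pulse must have zero spacing")
        if self.pulson_spacing < 0:
            raise ValueError("pulson_spacing must be >= 0")
        if not (2.6 <= self.pulson_voltage <= 3.7):
            raise ValueError(f"pulson voltage {self.pulson_voltage} V outside [2.6, 3.7]")


@dataclass(frozen=True)
class PulsePattern:
    """Pulson onsets/widths (us) within one pulse; period in ms."""

    pulson_onsets: tuple[float, ...]
    pulson_widths: tuple[float, ...]
    period_ms: float
    pulse_width: float

    @property
    def total_on_us(self) -> float:
        return sum(self.pulson_widths)


def build_pulse_pattern(params: StimParams) -> PulsePattern:
    """Chop one pulse into equal-width pulsons realizing the duty cycle.

    Each pulson has width (duty/100) * PW / n_pulsons; pulsons are separated
    by ``pulson_spacing`` and must fit inside the pulse width.
    """
    w = params.duty_cycle / 100.0 * params.pulse_width / params.n_pulsons
    span = params.n_pulsons * w + (params.n_pulsons - 1) * params.pulson_spacing
    if span > params.pulse_width + 1e-9:
        raise ValueError(
            f"pattern overflows pulse width: span {span:.1f} us > PW {params.pulse_width} us"
        )
    onsets = tuple(i * (w + params.pulson_spacing) for i in range(params.n_pulsons))
    return PulsePattern(
        pulson_onsets=onsets,
        pulson_widths=(w,) * params.n_pulsons,
        period_ms=1000.0 / params.frequency,
        pulse_width=params.pulse_width,
    )


@dataclass(frozen=True)
class CircuitParams:
    """R1 + (R2 || C1) cuff-nerve load; optional CPE variant (Q, alpha).

    R1 is the series/access resistance (the 330-ohm electrode contributes a
    small part of it); R2/C1 (or the CPE) describe the interface.
    """

    R1: float
    R2: float
    C1: float | None = None
    cpe_Q: float | None = None
    cpe_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("resistances must be positive")
        if self.C1 is not None and self.C1 <= 0:
            raise ValueError("C1 must be positive")
        if self.cpe_Q is not None and self.cpe_Q <= 0:
            raise ValueError("cpe_Q must be positive")
        if self.cpe_alpha is not None and not (0 < self.cpe_alpha <= 1):
            raise ValueError("cpe_alpha must be in (0, 1]")


#: Median cuff-load fit across animals: R1 1.58 kOhm, R2 44 kOhm, C1 2.6 uF.
PAPER_GRADE_MEDIAN_CIRCUIT = CircuitParams(R1=1580.0, R2=44_000.0, C1=2.6e-6)


@dataclass
class ImpedanceSpectrum:
    """Complex impedance vs frequency, 1 Hz - 10 kHz, strictly increasing."""

    frequencies: np.ndarray
    impedances: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedances = np.asarray(self.impedances, dtype=complex)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.frequencies[0] < 1.0 - 1e-9 or self.frequencies[-1] > 1e4 + 1e-6:
            raise ValueError("frequencies must lie in [1, 1e4] Hz")
        if not np.all(np.isfinite(self.impedances)):
            raise ValueError("impedances must be finite")


def circuit_impedance(circuit: CircuitParams, f, model: str = "rc"):
    """Z(f) of the load: R1 + R2/(1 + j*w*R2*C1), or the CPE analogue
    R1 + R2/(1 + (j*w)^alpha * R2 * Q); vectorized over ``f``."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f
    if model == "rc":
        if circuit.C1 is None:
            raise ValueError("rc model requires C1")
        z = circuit.R1 + circuit.R2 / (1.0 + 1j * w * circuit.R2 * circuit.C1)
    elif model == "cpe":
        if circuit.cpe_Q is None or circuit.cpe_alpha is None:
            raise ValueError("cpe model requires cpe_Q and cpe_alpha")
        z = circuit.R1 + circuit.R2 / (
            1.0 + (1j * w) ** circuit.cpe_alpha * circuit.R2 * circuit.cpe_Q
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    z = np.asarray(z)
    return z if z.ndim else complex(z)


def default_frequency_grid(n_per_decade: int = 10) -> np.ndarray:
    """Log-spaced EIS grid, 1 Hz - 10 kHz."""
    return np.logspace(0, 4, 4 * n_per_decade)


def simulate_spectrum(
    circuit: CircuitParams,
    f_grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    model: str = "rc",
) -> ImpedanceSpectrum:
    """Pointwise model impedance with optional proportional complex noise."""
    f = np.asarray(f_grid if f_grid is not None else default_frequency_grid(), dtype=float)
    z = circuit_impedance(circuit, f, model=model)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        z = z * (1.0 + noise_sigma * (rng.normal(size=len(f)) + 1j * rng.normal(size=len(f))))
    return ImpedanceSpectrum(f, z)


@dataclass
class CircuitFit:
    """Result of :func:`fit_circuit`: parameters, relative standard errors,
    convergence flag and the modulus-weighted residual norm."""

    params: CircuitParams
    rel_stderr: dict[str, float]
    converged: bool
    residual_norm: float
    model: str
    n_points: int


def _rc_residual(p, f, z, weights):
    c = CircuitParams(R1=p["R1"].value, R2=p["R2"].value, C1=p["C1"].value)
    dz = (circuit_impedance(c, f, "rc") - z) * weights
    return np.concatenate([dz.real, dz.imag])


def _cpe_residual(p, f, z, weights):
    c = CircuitParams(
        R1=p["R1"].value, R2=p["R2"].value, cpe_Q=p["Q"].value, cpe_alpha=p["alpha"].value
    )
    dz = (circuit_impedance(c, f, "cpe") - z) * weights
    return np.concatenate([dz.real, dz.imag])


def fit_circuit(
    spectrum: ImpedanceSpectrum, model: str = "rc", init: CircuitParams | None = None
) -> CircuitFit:
    """Levenberg-Marquardt fit of the equivalent circuit to a spectrum.

    Residuals are the stacked (Re, Im) differences weighted by 1/|Z_data|,
    the standard choice for spectra spanning decades of magnitude.
    Per-parameter relative standard errors come from the LM covariance.
    Non-convergence is flagged on the result, never raised.
    """
    n_par = 3 if model == "rc" else 4
    if len(spectrum.frequencies) < 2 * n_par:
        raise ValueError(f"need at least {2 * n_par} points to fit {n_par} parameters")
    f, z = spectrum.frequencies, spectrum.impedances
    weights = 1.0 / np.abs(z)
    p = lmfit.Parameters()
    if model == "rc":
        init = init or CircuitParams(R1=1e3, R2=1e4, C1=1e-6)
        p.add("R1", value=init.R1, min=1e-12)
        p.add("R2", value=init.R2, min=1e-12)
        p.add("C1", value=init.C1, min=1e-15)
        res = lmfit.minimize(_rc_residual, p, args=(f, z, weights), method="leastsq")
        fitted = CircuitParams(
            R1=res.params["R1"].value, R2=res.params["R2"].value, C1=res.params["C1"].value
        )
        names = {"R1": "R1", "R2": "R2", "C1": "C1"}
    elif model == "cpe":
        if init is None or init.cpe_Q is None or init.cpe_alpha is None:
            init = CircuitParams(R1=1e3, R2=1e4, cpe_Q=1e-6, cpe_alpha=0.9)
        p.add("R1", value=init.R1, min=1e-12)
        p.add("R2", value=init.R2, min=1e-12)
        p.add("Q", value=init.cpe_Q, min=1e-15)
        p.add("alpha", value=init.cpe_alpha, min=0.05, max=1.0)
        res = lmfit.minimize(_cpe_residual, p, args=(f, z, weights), method="leastsq")
        fitted = CircuitParams(
            R1=res.params["R1"].value,
            R2=res.params["R2"].value,
            cpe_Q=res.params["Q"].value,
            cpe_alpha=res.params["alpha"].value,
        )
        names = {"R1": "R1", "R2": "R2", "Q": "cpe_Q", "alpha": "cpe_alpha"}
    else:
        raise ValueError(f"unknown model {model!r}")
    rel = {}
    for pname, cname in names.items():
        par = res.params[pname]
        rel[cname] = (
            float(par.stderr / abs(par.value)) if par.stderr and par.value else float("nan")
        )
    return CircuitFit(
        params=fitted,
        rel_stderr=rel,
        converged=bool(res.success),
        residual_norm=float(np.sqrt(np.sum(np.asarray(res.residual) ** 2))),
        model=model,
        n_points=len(f),
    )


def _transient_segments(params: StimParams, circuit: CircuitParams):
    """Yield (on?, duration_s, ...) closed-form RC transient over one pulse.

    During a pulson the regulated voltage V drives R1 in series with R2||C1;
    between pulsons the source is off and C1 discharges through R2.  The
    capacitor voltage is carried across segments.
    """
    pattern = build_pulse_pattern(params)
    V, R1, R2 = params.pulson_voltage, circuit.R1, circuit.R2
    C1 = circuit.C1 if circuit.C1 is not None else 0.0
    vc = 0.0
    vc_inf = V * R2 / (R1 + R2)
    tau_on = C1 * R1 * R2 / (R1 + R2) if C1 > 0 else 0.0
    tau_off = C1 * R2 if C1 > 0 else 0.0
    for k, (onset, width) in enumerate(zip(pattern.pulson_onsets, pattern.pulson_widths)):
        w = width * 1e-6
        yield ("on", w, vc, vc_inf, tau_on, V, R1)
        if tau_on > 0:
            vc = vc_inf + (vc - vc_inf) * math.exp(-w / tau_on)
        else:
            vc = vc_inf if w > 0 else vc
        if k + 1 < params.n_pulsons and params.pulson_spacing > 0:
            gap = params.pulson_spacing * 1e-6
            yield ("off", gap, vc, 0.0, tau_off, V, R1)
            if tau_off > 0:
                vc *= math.exp(-gap / tau_off)


def peak_current(
    params: StimParams, circuit: CircuitParams, n_samples: int = 200
) -> tuple[float, np.ndarray, np.ndarray]:
    """Onset current and the RC transient over the first pulson.

    At pulse onset the uncharged C1 shorts R2, so the instantaneous current
    is V/R1.  Returns (peak mA, time us, current mA) with the current decaying
    toward V/(R1+R2) with the on-phase time constant.
    """
    pattern = build_pulse_pattern(params)
    V, R1, R2 = params.pulson_voltage, circuit.R1, circuit.R2
    C1 = circuit.C1 if circuit.C1 is not None else 0.0
    w = pattern.pulson_widths[0] * 1e-6
    t = np.linspace(0.0, w, n_samples)
    if C1 > 0:
        tau = C1 * R1 * R2 / (R1 + R2)
        vc_inf = V * R2 / (R1 + R2)
        vc = vc_inf * (1.0 - np.exp(-t / tau))
    else:
        vc = np.full_like(t, V * R2 / (R1 + R2))
        vc[0] = 0.0
    i = (V - vc) / R1
    return float(V / R1 * 1e3), t * 1e6, i * 1e3


def charge_per_pulse(params: StimParams, circuit: CircuitParams) -> float:
    """Charge (uC) injected over all pulsons of one pulse.

    Integrates the RC transient current analytically segment by segment,
    carrying the capacitor state across pulson gaps (discharge through R2).
    Monotone increasing in duty cycle and pulse width.
    """
    q = 0.0
    for kind, dt, vc0, vc_inf, tau, V, R1 in _transient_segments(params, circuit):
        if kind != "on":
            continue
        if tau > 0:
            int_vc = vc_inf * dt + (vc0 - vc_inf) * tau * (1.0 - math.exp(-dt / tau))
        else:
            int_vc = vc_inf * dt
        q += (V * dt - int_vc) / R1
    return q * 1e6
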