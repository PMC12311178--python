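"""Configurable stand-in for the anesthetized subject.

Maps a stimulation setting to a steady-state percent heart-rate drop through
a separable power-law dose-response surface,

    dHR% = A_max * (f/f_ref)^gf * (d/d_ref)^gd * (PW/pw_ref)^gpw - tachy_offset,

calibrated so the reference configuration reproduces the two open-loop
anchors: ~13% bradycardia at (20 Hz, 100% duty, reference PW) and < 2% of
baseline at low frequency / low duty.  The drop relaxes toward its target
with first-order dynamics (tau_on during stimulation, tau_off during rest),
and each 5-s analysis window receives independent Gaussian heart-rate-
variability noise.

Scenario presets rescale the surface so a closed-loop run started at the
adverse initialization (20 Hz, 1024 us, 100%) opens with the printed
first-epoch reductions (13 / 10 / 6%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stim_model import StimParams

__all__ = [
    "PlantConfig",
    "PlantState",
    "steady_response",
    "hr_dynamics_step",
    "simulate_epoch_hr",
    "scenario_preset",
    "SCENARIO_PRESETS",
    "EPOCH_WINDOWS",
    "ACTIVE_WINDOWS",
]

# 14 s ON + 66 s OFF = 80 s = 16 windows of 5 s; the active phase covers
# windows 0-2 (0-15 s grid cells, the 14 s ON rounded up to the window grid).
EPOCH_WINDOWS = 16
ACTIVE_WINDOWS = 3
WINDOW_S = 5.0


@dataclass(frozen=True)
class PlantConfig:
    """Dose-response surface, dynamics and HRV noise of the simulated subject."""

    baseline_hr: float = 80.0
    a_max: float = 13.0
    gamma_f: float = 1.2
    gamma_d: float = 0.8
    gamma_pw: float = 0.5
    f_ref: float = 20.0
    d_ref: float = 100.0
    pw_ref: float = 512.0
    tachy_offset: float = 0.0
    tau_on: float = 3.0
    tau_off: float = 8.0
    hrv_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_max < 0:
            raise ValueError("a_max must be >= 0")
        if min(self.gamma_f, self.gamma_d, self.gamma_pw) <= 0:
            raise ValueError("shape exponents must be positive")
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("time constants must be positive")
        if self.hrv_sigma < 0:
            raise ValueError("hrv_sigma must be >= 0")


@dataclass
class PlantState:
    """Current percent HR drop and the plant's RNG."""

    drop: float = 0.0
    t: float = 0.0
    rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self.rng is None:
            self.rng = np.random.default_rng(0)


def make_state(cfg: PlantConfig) -> PlantState:
    return PlantState(drop=0.0, t=0.0, rng=np.random.default_rng(int(cfg.seed)))


def steady_response(cfg: PlantConfig, params: StimParams) -> float:
    """Steady-state percent HR drop (positive = bradycardia) for ``params``.

    Strictly increasing in frequency, duty cycle and pulse width; with
    ``tachy_offset`` = 0 the plant is purely bradycardic (drop clipped at 0).
    """
    drive = (
        cfg.a_max
        * (params.frequency / cfg.f_ref) ** cfg.gamma_f
        * (params.duty_cycle / cfg.d_ref) ** cfg.gamma_d
        * (params.pulse_width / cfg.pw_ref) ** cfg.gamma_pw
    )
    return max(drive - cfg.tachy_offset, -cfg.tachy_offset)


def hr_dynamics_step(
    state: PlantState, cfg: PlantConfig, target_drop: float, dt: float, stim_on: bool
) -> PlantState:
    """First-order relaxation of the drop toward its target.

    drop' = drop + (target - drop) * (1 - exp(-dt/tau)), tau = tau_on while
    stimulating, tau_off (target 0) otherwise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = cfg.tau_on if stim_on else cfg.tau_off
    target = target_drop if stim_on else 0.0
    new_drop = state.drop + (target - state.drop) * (1.0 - np.exp(-dt / tau))
    return PlantState(drop=float(new_drop), t=state.t + dt, rng=state.rng)


def simulate_epoch_hr(
    state: PlantState, cfg: PlantConfig, params: StimParams
) -> tuple[np.ndarray, PlantState]:
    """One 14 s ON + 66 s OFF epoch on the 5-s window clock.

    Returns 16 window HR values, HR_w = baseline * (1 - drop_w/100) + HRV
    noise, where drop_w is the relaxed drop at the end of each window, and
    the updated plant state.
    """
    target = steady_response(cfg, params)
    hrs = np.empty(EPOCH_WINDOWS)
    for w in range(EPOCH_WINDOWS):
        state = hr_dynamics_step(state, cfg, target, WINDOW_S, stim_on=w < ACTIVE_WINDOWS)
        hr = cfg.baseline_hr * (1.0 - state.drop / 100.0)
        if cfg.hrv_sigma > 0:
            hr += state.rng.normal(0.0, cfg.hrv_sigma)
        hrs[w] = hr
    return hrs, state


def rest_windows(state: PlantState, cfg: PlantConfig, n_windows: int) -> tuple[np.ndarray, PlantState]:
    """Stimulation-free windows (pre-run rest period)."""
    hrs = np.empty(n_windows)
    for w in range(n_windows):
        state = hr_dynamics_step(state, cfg, 0.0, WINDOW_S, stim_on=False)
        hr = cfg.baseline_hr * (1.0 - state.drop / 100.0)
        if cfg.hrv_sigma > 0:
            hr += state.rng.normal(0.0, cfg.hrv_sigma)
        hrs[w] = hr
    return hrs, state


# Initial percent HR reductions of the in-vivo closed-loop scenarios,
# realized at the adverse init (20 Hz, 100% duty, 1024 us PW).
SCENARIO_PRESETS: dict[str, dict] = {
    "reference": {"initial_drop": 13.0, "hrv_sigma": 0.0, "rescale": False},
    "reference_noisy": {"initial_drop": 13.0, "hrv_sigma": 0.5, "rescale": False},
    "open_incision": {"initial_drop": 10.0, "hrv_sigma": 0.5, "rescale": True},
    "closed_incision": {"initial_drop": 6.0, "hrv_sigma": 0.5, "rescale": True},
}

_ADVERSE_PW = 1024.0


def scenario_preset(
    name: str, hrv_sigma: float | None = None, seed: int = 0
) -> PlantConfig:
    """Named plant configurations.

    ``reference``/``reference_noisy`` keep the open-loop calibration
    (A_max = 13 at the reference pulse width); ``open_incision`` and
    ``closed_incision`` rescale A_max so the steady drop at the adverse
    closed-loop initialization equals the printed 10% / 6% first reductions.
    """
    if name not in SCENARIO_PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(SCENARIO_PRESETS)}")
    p = SCENARIO_PRESETS[name]
    cfg = PlantConfig(seed=seed, hrv_sigma=p["hrv_sigma"])
    if p["rescale"]:
        pw_gain = (_ADVERSE_PW / cfg.pw_ref) ** cfg.gamma_pw
        cfg = replace(cfg, a_max=p["initial_drop"] / pw_gain)
    if hrv_sigma is not None:
        cfg = replace(cfg, hrv_sigma=hrv_sigma)
    return cfg
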