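"""State-based, discrete-time stimulation controller.

Each 14 s active phase yields one percent-HR-drop measurement (worst-case:
the minimum active-window HR against the pre-stimulation baseline).  The
response is classified against a trip level combining two rules:

* the bradycardia threshold, one-fifth or one-tenth of the maximum HR
  response observed so far in the run, and
* the steady-state design band (2-4% of baseline, default 2.5%).

The effective trip level is the tighter of the two once a response has been
observed — the threshold may tighten the band but never loosen it past the
design target, which keeps classification consistent with the steady-state
declaration and drives the run to a final drop inside the band.

On bradycardia the controller de-escalates exactly one parameter per rest
phase: duty cycle steps down its grid first, then frequency (duty-first
ordering); tachycardia mirrors the most recent down-step.  Steady state is
declared after ``consecutive_required`` in-band active phases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .stim_model import StimParams

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "ResponseClass",
    "compute_threshold",
    "measure_response",
    "classify_response",
    "next_params",
    "is_steady",
    "initial_state",
]


class ResponseClass(str, enum.Enum):
    BRADYCARDIA = "bradycardia"
    TACHYCARDIA = "tachycardia"
    STEADY = "steady"


class Action(str, enum.Enum):
    DUTY_DOWN = "duty_down"
    DUTY_UP = "duty_up"
    FREQ_DOWN = "freq_down"
    FREQ_UP = "freq_up"
    HOLD = "hold"


@dataclass(frozen=True)
class ControllerConfig:
    """Grids, thresholding and steady-state policy of the controller."""

    freq_grid: tuple[float, ...] = (20.0, 15.0, 10.0, 5.0, 2.0, 1.0)
    duty_grid: tuple[float, ...] = (100.0, 50.0, 25.0, 12.5)
    pw: float = 1024.0
    threshold_divisor: float = 5.0
    steady_band: float = 2.5
    consecutive_required: int = 2
    max_iterations: int = 30
    aggregation: str = "min"  # worst-case window; "mean" available
    pulson_voltage: float = 3.3

    def __post_init__(self) -> None:
        for grid, name in ((self.freq_grid, "freq_grid"), (self.duty_grid, "duty_grid")):
            if len(grid) == 0:
                raise ValueError(f"{name} must be nonempty")
            if any(b >= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly decreasing")
        if self.threshold_divisor not in (5.0, 10.0, 5, 10):
            raise ValueError("threshold_divisor must be 5 or 10")
        if not (2.0 <= self.steady_band <= 4.0):
            raise ValueError("steady_band must be in [2, 4] percent")
        if self.consecutive_required < 1:
            raise ValueError("consecutive_required must be >= 1")
        if self.aggregation not in ("min", "mean"):
            raise ValueError("aggregation must be 'min' or 'mean'")

    def make_params(self, frequency: float, duty_cycle: float) -> StimParams:
        return StimParams(
            frequency=frequency,
            pulse_width=self.pw,
            duty_cycle=duty_cycle,
            pulson_voltage=self.pulson_voltage,
        )

    def initial_params(self) -> StimParams:
        """Adverse initialization: top of both grids at the configured PW."""
        return self.make_params(self.freq_grid[0], self.duty_grid[0])


@dataclass
class ControllerState:
    params: StimParams
    max_observed_drop: float = 0.0
    threshold: float = 0.0  # max_observed_drop / divisor, refreshed per epoch
    steady_count: int = 0
    iteration: int = 0  # parameter updates applied so far
    last_action: Action = Action.HOLD
    last_down: Action | None = None
    floor_reached: bool = False


def initial_state(cfg: ControllerConfig) -> ControllerState:
    return ControllerState(params=cfg.initial_params())


def compute_threshold(max_observed_drop: float, divisor: float) -> float:
    """Bradycardia threshold: max observed HR response divided by 5 or 10."""
    if max_observed_drop < 0:
        raise ValueError("max_observed_drop must be >= 0")
    return max_observed_drop / divisor


def measure_response(
    active_window_hrs: np.ndarray, baseline: float, aggregation: str = "min"
) -> float:
    """Percent HR drop of one active phase (negative = tachycardia).

    ``min`` aggregation takes the worst (lowest-HR) active window; ``mean``
    averages the windows.  Raises if all active windows are missing.
    """
    hrs = np.asarray(active_window_hrs, dtype=float)
    hrs = hrs[np.isfinite(hrs)]
    if len(hrs) == 0:
        raise ValueError("no-measurement: all active-phase windows missing")
    agg = np.min(hrs) if aggregation == "min" else np.mean(hrs)
    return float((baseline - agg) / baseline * 100.0)


def _trip_level(state: ControllerState, cfg: ControllerConfig) -> float:
    thr = compute_threshold(state.max_observed_drop, cfg.threshold_divisor)
    return min(thr, cfg.steady_band) if thr > 0 else cfg.steady_band


def classify_response(
    drop: float, state: ControllerState, cfg: ControllerConfig
) -> ResponseClass:
    """Classify an active-phase drop against the effective trip level."""
    trip = _trip_level(state, cfg)
    if drop > trip:
        return ResponseClass.BRADYCARDIA
    if drop < -trip:
        return ResponseClass.TACHYCARDIA
    return ResponseClass.STEADY


def _grid_index(grid: tuple[float, ...], value: float) -> int:
    for i, g in enumerate(grid):
        if abs(g - value) < 1e-9:
            return i
    raise ValueError(f"value {value} not on grid {grid}")


def next_params(
    state: ControllerState, cls: ResponseClass, cfg: ControllerConfig
) -> tuple[StimParams, Action]:
    """One-parameter update rule (reference decision tree).

    bradycardia: duty down one level; at the duty floor, frequency down one;
    at both floors, hold (floor flag set by the caller).  tachycardia: invert
    the most recent down-step, saturating at the grid ceilings.  steady: hold.
    Exactly one field ever differs from the current params.
    """
    p = state.params
    fi = _grid_index(cfg.freq_grid, p.frequency)
    di = _grid_index(cfg.duty_grid, p.duty_cycle)
    if cls is ResponseClass.STEADY:
        return p, Action.HOLD
    if cls is ResponseClass.BRADYCARDIA:
        if di + 1 < len(cfg.duty_grid):
            return cfg.make_params(p.frequency, cfg.duty_grid[di + 1]), Action.DUTY_DOWN
        if fi + 1 < len(cfg.freq_grid):
            return cfg.make_params(cfg.freq_grid[fi + 1], p.duty_cycle), Action.FREQ_DOWN
        return p, Action.HOLD  # both floors: saturate
    # tachycardia: mirror the most recent down-step
    if state.last_down is Action.FREQ_DOWN and fi > 0:
        return cfg.make_params(cfg.freq_grid[fi - 1], p.duty_cycle), Action.FREQ_UP
    if di > 0:
        return cfg.make_params(p.frequency, cfg.duty_grid[di - 1]), Action.DUTY_UP
    if fi > 0:
        return cfg.make_params(cfg.freq_grid[fi - 1], p.duty_cycle), Action.FREQ_UP
    return p, Action.HOLD  # at the ceiling


def is_steady(state: ControllerState, cfg: ControllerConfig) -> bool:
    """Steady state: enough consecutive in-band active phases."""
    return state.steady_count >= cfg.consecutive_required
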