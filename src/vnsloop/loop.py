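"""Closed-loop orchestration on the 14 s ON / 66 s OFF protocol clock.

Schedules 80-s epochs (16 windows of 5 s, active phase in windows 0-2),
wires plant -> (optional synthetic ECG -> DSP) -> controller -> plant, and
persists fully reproducible run records.

Two sensing modes:

* ``direct_hr`` — the plant's per-window HR values feed the controller
  directly (the fast path for statistics).
* ``full_stack`` — each epoch's HR trajectory drives the ECG generator and
  the heart rate is decoded through the full DSP chain (filter, adaptive
  R-peak detection, 5-s median), exercising the complete pipeline.

A 30-s pre-stimulation rest period provides the first epoch's baseline
(mean of the two most recent rest windows).  An abort predicate (default:
drop > 30%) stands in for the manual-intervention hook of a supervised
experiment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import controller as ctl
from . import plant as plant_mod
from .controller import Action, ControllerConfig, ResponseClass
from .ecg_synth import NoiseConfig, make_hr_profile, synthesize_ecg
from .hr_dsp import FilterSpec, apply_filters, detect_r_peaks, hr_from_peaks_windowed
from .plant import ACTIVE_WINDOWS, EPOCH_WINDOWS, WINDOW_S, PlantConfig
from .stim_model import StimParams

__all__ = [
    "EpochRecord",
    "RunRecord",
    "run_closed_loop",
    "write_run_record",
    "read_run_record",
    "standard_cohort",
    "openloop_sweep",
]

SCHEMA_VERSION = 1
PRE_REST_WINDOWS = 6  # 30 s pre-stimulation rest


@dataclass
class EpochRecord:
    """One stimulation cycle: parameters, windows, decision."""

    epoch_index: int
    params: StimParams
    baseline: float
    window_hrs: list[float]
    drop: float
    response_class: str
    action: str
    steady_flag: bool


@dataclass
class RunRecord:
    """A full closed-loop run: config snapshot, epochs, outcome."""

    plant_cfg: PlantConfig
    controller_cfg: ControllerConfig
    mode: str
    seed: int
    epochs: list[EpochRecord] = field(default_factory=list)
    status: str = "unterminated"
    n_updates: int = 0
    schema_version: int = SCHEMA_VERSION

    @property
    def first_drop(self) -> float:
        return self.epochs[0].drop

    @property
    def last_drop(self) -> float:
        return self.epochs[-1].drop

    @property
    def drops(self) -> np.ndarray:
        return np.array([e.drop for e in self.epochs])


def _decode_epoch_full_stack(
    window_hrs: np.ndarray, lead_hr: float, seed: int, epoch_index: int
) -> np.ndarray:
    """Re-extract epoch window HRs through synth ECG + DSP.

    The epoch's window HR trajectory becomes a stepped profile padded by one
    window on each side (so filter edge transients and the first R-R interval
    fall outside the scored region), rendered to ECG and decoded.
    """
    pad = WINDOW_S
    segs = [(0.0, float(lead_hr))]
    segs += [(pad + WINDOW_S * w, float(h)) for w, h in enumerate(window_hrs)]
    profile = make_hr_profile(segs, interpolation="hold")
    duration = pad + EPOCH_WINDOWS * WINDOW_S + pad
    noise = NoiseConfig(0.0, 0.3, 0.0, 0.0, seed=(seed * 1009 + epoch_index) % 2**31)
    trace = synthesize_ecg(profile, duration, fs=200.0, noise=noise)
    filt = apply_filters(trace, FilterSpec())
    peaks = detect_r_peaks(filt)
    series = hr_from_peaks_windowed(peaks, WINDOW_S)
    return series.hr_bpm[1 : 1 + EPOCH_WINDOWS]


def run_closed_loop(
    plant_cfg: PlantConfig,
    controller_cfg: ControllerConfig | None = None,
    mode: str = "direct_hr",
    seed: int = 0,
    abort_drop: float = 30.0,
) -> RunRecord:
    """Run the closed loop from the adverse initialization to termination.

    Status is one of ``steady`` (in-band for the required consecutive
    phases), ``floor_reached`` (bradycardia persists at both grid floors),
    ``max_iterations``, or ``aborted`` (drop beyond ``abort_drop``).
    Identical (configs, seed) give identical records.
    """
    controller_cfg = controller_cfg or ControllerConfig()
    if mode not in ("direct_hr", "full_stack"):
        raise ValueError(f"unknown mode {mode!r}")
    pcfg = dataclasses.replace(plant_cfg, seed=(plant_cfg.seed + seed) % 2**31)
    pstate = plant_mod.make_state(pcfg)
    cstate = ctl.initial_state(controller_cfg)
    record = RunRecord(plant_cfg=pcfg, controller_cfg=controller_cfg, mode=mode, seed=seed)

    rest_hrs, pstate = plant_mod.rest_windows(pstate, pcfg, PRE_REST_WINDOWS)
    history = list(rest_hrs)

    for epoch in range(controller_cfg.max_iterations):
        finite = [h for h in history if np.isfinite(h)]
        baseline = float(np.mean(finite[-2:]))
        window_hrs, pstate = plant_mod.simulate_epoch_hr(pstate, pcfg, cstate.params)
        if mode == "full_stack":
            window_hrs = _decode_epoch_full_stack(window_hrs, finite[-1], seed, epoch)
        try:
            drop = ctl.measure_response(
                window_hrs[:ACTIVE_WINDOWS], baseline, controller_cfg.aggregation
            )
        except ValueError:
            # fail-safe: no usable active-phase windows -> hold, no update
            record.epochs.append(
                EpochRecord(
                    epoch_index=epoch,
                    params=cstate.params,
                    baseline=baseline,
                    window_hrs=[float(h) for h in window_hrs],
                    drop=float("nan"),
                    response_class="no_measurement",
                    action=Action.HOLD.value,
                    steady_flag=False,
                )
            )
            history.extend(float(h) for h in window_hrs)
            continue
        cstate.max_observed_drop = max(cstate.max_observed_drop, max(drop, 0.0))
        cstate.threshold = ctl.compute_threshold(
            cstate.max_observed_drop, controller_cfg.threshold_divisor
        )
        cls = ctl.classify_response(drop, cstate, controller_cfg)
        cstate.steady_count = cstate.steady_count + 1 if cls is ResponseClass.STEADY else 0
        new_params, action = ctl.next_params(cstate, cls, controller_cfg)
        steady_now = ctl.is_steady(cstate, controller_cfg)
        at_floor = (
            cls is ResponseClass.BRADYCARDIA
            and action is Action.HOLD
        )
        record.epochs.append(
            EpochRecord(
                epoch_index=epoch,
                params=cstate.params,
                baseline=baseline,
                window_hrs=[float(h) for h in window_hrs],
                drop=drop,
                response_class=cls.value,
                action=action.value,
                steady_flag=steady_now,
            )
        )
        history.extend(float(h) for h in window_hrs)
        if steady_now:
            record.status = "steady"
            break
        if drop > abort_drop:
            record.status = "aborted"
            break
        if at_floor:
            cstate.floor_reached = True
            record.status = "floor_reached"
            break
        if action is not Action.HOLD:
            cstate.iteration += 1
            record.n_updates += 1
            cstate.last_action = action
            if action in (Action.DUTY_DOWN, Action.FREQ_DOWN):
                cstate.last_down = action
        cstate.params = new_params
    else:
        record.status = "max_iterations"
    return record


# ---------------------------------------------------------------------------
# persistence

def _params_to_dict(p: StimParams) -> dict:
    return dataclasses.asdict(p)


def write_run_record(record: RunRecord, path) -> None:
    """JSON persistence; NaN windows are stored as null."""
    def clean(x):
        return None if isinstance(x, float) and not np.isfinite(x) else x

    doc = {
        "schema_version": record.schema_version,
        "mode": record.mode,
        "seed": record.seed,
        "status": record.status,
        "n_updates": record.n_updates,
        "plant_cfg": dataclasses.asdict(record.plant_cfg),
        "controller_cfg": dataclasses.asdict(record.controller_cfg),
        "epochs": [
            {
                "epoch_index": e.epoch_index,
                "params": _params_to_dict(e.params),
                "baseline": e.baseline,
                "window_hrs": [clean(h) for h in e.window_hrs],
                "drop": e.drop,
                "response_class": e.response_class,
                "action": e.action,
                "steady_flag": e.steady_flag,
            }
            for e in record.epochs
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_run_record(path) -> RunRecord:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("schema_version", "status", "epochs", "plant_cfg", "controller_cfg"):
        if key not in doc:
            raise ValueError(f"malformed run record: missing field {key!r}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {doc['schema_version']}")
    ccfg_doc = dict(doc["controller_cfg"])
    for k in ("freq_grid", "duty_grid"):
        ccfg_doc[k] = tuple(ccfg_doc[k])
    record = RunRecord(
        plant_cfg=PlantConfig(**doc["plant_cfg"]),
        controller_cfg=ControllerConfig(**ccfg_doc),
        mode=doc["mode"],
        seed=doc["seed"],
        status=doc["status"],
        n_updates=doc["n_updates"],
    )
    for e in doc["epochs"]:
        record.epochs.append(
            EpochRecord(
                epoch_index=e["epoch_index"],
                params=StimParams(**e["params"]),
                baseline=e["baseline"],
                window_hrs=[float("nan") if h is None else h for h in e["window_hrs"]],
                drop=e["drop"],
                response_class=e["response_class"],
                action=e["action"],
                steady_flag=e["steady_flag"],
            )
        )
    return record


# ---------------------------------------------------------------------------
# cohorts and sweeps

COHORT_PRESETS = ("reference", "reference_noisy", "open_incision", "closed_incision")


def standard_cohort(
    seed: int = 1, hrv_sigma: float = 0.5, mode: str = "direct_hr"
) -> list[RunRecord]:
    """Eight seeded noisy runs: two per scenario preset.

    All runs use the adverse initialization and HRV noise (default 0.5 bpm
    per window); per-run seeds derive from ``seed``.
    """
    records = []
    for i in range(8):
        preset = COHORT_PRESETS[i % len(COHORT_PRESETS)]
        pcfg = plant_mod.scenario_preset(preset, hrv_sigma=hrv_sigma, seed=0)
        run_seed = (seed * 101 + i + 1) % 2**31
        records.append(run_closed_loop(pcfg, ControllerConfig(), mode=mode, seed=run_seed))
    return records


def openloop_sweep(
    plant_cfg: PlantConfig,
    freqs=(1.0, 2.0, 5.0, 10.0, 15.0, 20.0),
    duties=(12.5, 25.0, 50.0, 100.0),
    pw: float = 512.0,
):
    """Steady-state dose-response surface (open-loop style)."""
    import pandas as pd

    rows = []
    for f in freqs:
        for d in duties:
            p = StimParams(frequency=f, pulse_width=pw, duty_cycle=d)
            rows.append(
                {"frequency_hz": f, "duty_pct": d, "pw_us": pw,
                 "drop_pct": plant_mod.steady_response(plant_cfg, p)}
            )
    return pd.DataFrame(rows)
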