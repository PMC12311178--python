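# vnsloop

A desk-scale simulator for **closed-loop vagus nerve stimulation (VNS)**.

Therapeutic VNS is limited by its main off-target effect, bradycardia: at
high stimulation frequency and duty cycle the heart rate (HR) can drop far
enough to require medical supervision. A closed-loop stimulator senses the
HR response and automatically de-escalates its own parameters until the
response sits at the *neural fulcrum* — the operating point where
stimulation still activates the nerve but the net HR change stays inside a
small steady-state band (2–4% of baseline). `vnsloop` reproduces that whole
loop in software so the convergence behaviour, the signal chain and the
outcome statistics can be studied, tested and extended without hardware or
animals.

The package is aimed at neuromodulation and biosignal-processing
researchers and at control engineers prototyping physiological closed-loop
policies.

## What is simulated

* **`ecg_synth`** — synthetic Lead-I-style ECG and left-ventricular-pressure
  traces with an exact, analytically invertible beat clock: beat *k* occurs
  when ∫₀ᵗ r(τ)/60 dτ = k for a prescribed instantaneous rate profile r(t).
* **`hr_dsp`** — the control unit's sensing chain: a 24th-order high-pass
  FIR (4 Hz) cascaded with a 48th-order low-pass FIR (45 Hz) at 200 S/s,
  adaptive R-peak detection, a robust 5-s windowed **median HR** (one value
  per window), baseline HR = mean of the two most recent pre-stimulation
  windows, and the agreement metric
  `mean(|HR_sensed − HR_ref| / HR_ref) × 100%`.
* **`stim_model`** — pulse "pulson" patterns (duty cycle = Σ pulson widths /
  pulse width, the charge-injection proxy), and the cuff-nerve load
  `Z(ω) = R₁ + R₂/(1 + jωR₂C₁)` (or a constant-phase-element variant) with
  spectrum simulation, Levenberg–Marquardt fitting, onset currents and
  per-pulse charge.
* **`plant`** — the simulated subject: a separable power-law dose-response
  surface `ΔHR% = A_max (f/f_ref)^γf (d/d_ref)^γd (PW/PW_ref)^γpw`
  calibrated to ~13% bradycardia at (20 Hz, 100% duty) and < 2% at low
  settings, with first-order onset/recovery dynamics and per-window HRV
  noise.
* **`controller`** — the state-based policy: classify each active-phase
  response against a trip level (the bradycardia threshold, max observed
  response / 5 or 10, never looser than the steady band), then update
  **exactly one** parameter per rest phase — duty cycle down first, then
  frequency — and declare steady state after consecutive in-band responses.
* **`loop`** — orchestration on the protocol clock (14 s ON + 66 s OFF =
  16 windows of 5 s), in `direct_hr` mode or `full_stack` mode (plant →
  synthetic ECG → DSP → controller), with reproducible JSON run records.
* **`trend_stats`** — the outcome statistics: a one-sided downward
  Mann-Kendall trend test on per-epoch drop magnitudes (exact permutation
  null for short sequences), per-run first/last drop ratios and cohort
  summaries.

## Worked example

Run one closed-loop simulation from the adverse initialization (20 Hz,
1024 µs, 100% duty) against the "open incision" scenario (first-epoch drop
calibrated to 10%, HRV noise 0.5 bpm):

```bash
$ vnsloop simulate --preset open_incision --seed 2 --out run_open.json
status=steady updates=4 first_drop=10.58% last_drop=0.36% seed=2
```

The controller needed 4 parameter updates to bring a 10.6% bradycardic
response into the steady-state band; the final stimulated epoch drops HR by
only 0.36%. The per-epoch drop sequence and its trend:

```python
>>> from vnsloop import loop, trend_stats
>>> rec = loop.read_run_record("run_open.json")
>>> [round(d, 2) for d in rec.drops]
[10.58, 6.63, 3.65, 1.9, 2.73, 1.38, 0.36]
>>> s = trend_stats.run_summary(rec)
>>> s.trend.S, round(s.trend.p_one_sided_down, 4)
(-19, 0.0014)
```

The Mann-Kendall statistic S = −19 (out of ±21 possible for 7 epochs) with
an exact one-sided p = 0.0014: the HR drops get significantly smaller as
the controller walks toward the fulcrum.

Other entry points: `vnsloop synth` (ECG/LVP CSV pairs from a YAML rate
profile), `vnsloop extract-hr`, `vnsloop openloop-sweep` (dose-response
surface), `vnsloop simulate-eis` / `vnsloop fit-eis`, and `vnsloop analyze`
(cohort statistics over a directory of run records).

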