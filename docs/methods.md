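# Methods

This note documents the models inside `vnsloop`, the defaults that matter,
and the design choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic biosignals (`ecg_synth`)

**Beat clock.** A heart-rate profile r(t) (bpm) is piecewise constant
("hold") or piecewise linear. The cumulative beat count
B(t) = (1/60)∫₀ᵗ r dτ is then piecewise linear/quadratic, and beat k
(k = 0, 1, …, with beat 0 at t = 0) is placed where B(t) = k by solving the
segment polynomial in closed form. Beat placement by rate integration, not
per-beat R-R sampling, makes window-level quantities analytic: a stepped
profile aligned to the 5-s grid yields per-window median HRs equal to the
profile values, which is what the end-to-end DSP recovery tests exploit.
The realized beat count can differ from ⌊B(duration)⌋ by at most one beat
(boundary beats), and the property tests assert exactly that bound.

**Morphology.** Each beat renders a raised-cosine R wave (default width
80 ms, amplitude 1.0 in millivolt-scale arbitrary units) with optional P
(0.12, placed at −0.22 R-R) and T (0.25, +0.32 R-R) bumps — QRS dominance
(R ≥ 3× any other deflection) without any claim of 12-lead realism. The
LVP channel renders one pressure pulse per beat (baseline 8, amplitude 92
in mmHg-scale arbitrary units) whose half-cosine upstroke is centred on
the beat time, so the 50%-level rising edge *is* the beat time; only
timing matters downstream.

**Noise.** Three standard confounders, each seeded: sinusoidal baseline
wander (default 0.1 units at 0.3 Hz — inside the high-pass stopband),
white sample noise (default σ = 0.05, i.e. R/20), and per-beat R-R jitter
(default 2% of the local interval, clipped at 40% to preserve ordering).
The jitter stream is drawn from a sub-seed shared by the ECG and LVP
channels, so both channels keep a common beat clock while their additive
noise streams stay independent.

**What the generator does not emulate:** arrhythmia, respiration coupling,
electrode motion artifacts, realistic porcine amplitudes. Passing the
fidelity benchmarks therefore shows the DSP chain is correct and robust to
the modelled confounders, not that it is field-ready for arbitrary
recordings.

## HR extraction (`hr_dsp`)

**Filters.** "24th-order" and "48th-order" are read as filter order, so
taps = order + 1 (25 and 49), both linear phase. The high-pass is built as
δ − LP₀ where LP₀ is a least-squares low-pass normalized to unit DC gain;
this pins the high-pass DC gain to exactly zero and, at only 25 taps,
keeps the response flat (within ripple) from about 1.5× the 4 Hz cutoff
upward, with the transition band spanning cutoff ± cutoff/2. The 45 Hz
low-pass is a Hamming-window sinc with its −6 dB point at the cutoff.
Filtering is offline, so each stage uses a centred convolution: the
(taps−1)/2 group delay is compensated exactly and peak times are unbiased
(a real-time implementation has latency; latency is irrelevant here).

**R-peak detection.** Candidates are local maxima at least 200 ms apart
(refractory). A candidate is accepted when it exceeds θ × L(t), where L is
a running peak-amplitude level (EMA with weight 0.25 on acceptance) that
decays exponentially with a 2-s time constant since the last accepted
peak; θ defaults to 0.5. This is the minimal classical adaptive-threshold
scheme; θ, decay and refractory are arguments. Accepted peak times are
refined to sub-sample precision by parabolic interpolation through the
three samples around the maximum — on the raised-cosine template this
reduces the timing error from ±2.5 ms (half a sample) to microseconds.

**Windowed HR.** Windows are half-open [5k, 5(k+1)) s aligned to t = 0
(the protocol's window/trigger alignment is a convention here). Each R-R
interval contributes 60/RR bpm to the window containing its *ending*
peak; the window HR is the median of its contributions, NaN when no
interval ends in the window or the median falls outside (20, 300) bpm.
Missing windows propagate as NaN and the controller treats an
unmeasurable active phase as "hold" (fail-safe). LVP extraction finds
mid-level upward crossings of the lightly smoothed pressure (5-sample
moving average, 200 ms refractory, linear sub-sample interpolation) and
applies a 3-point moving median to the edge-to-edge rates before
windowing.

**Baseline and agreement.** Baseline HR is the arithmetic mean of the two
most recent non-missing windows that end at or before stimulation onset.
The agreement metric is mean(|sensed − ref| / ref) × 100% over common
non-missing windows.

## Stimulation and load (`stim_model`)

**Pulse patterns.** A pulse of width PW at duty cycle d carries n equal
pulsons of width (d/100)·PW/n separated by `pulson_spacing`; equal widths
because nothing suggests otherwise. Patterns whose span exceeds PW are
rejected. The duty-cycle identity Σwidths/PW = d/100 holds exactly by
construction and is property-tested. At 100% duty any nonzero spacing
overflows, so the controller emits traditional rectangular pulses
(n = 1, spacing 0); pulson chopping remains available on `StimParams`.

**Load model.** Z(ω) = R₁ + R₂/(1 + jωR₂C₁), or with a constant phase
element Z(ω) = R₁ + R₂/(1 + (jω)^α R₂Q). The bundled
`PAPER_GRADE_MEDIAN_CIRCUIT` (1.58 kΩ, 44 kΩ, 2.6 µF) is the median
across-animal cuff-load fit. Spectra live on a log grid, 10
points/decade, 1 Hz–10 kHz, with optional proportional complex noise.

**Fitting.** Levenberg–Marquardt (MINPACK via lmfit) on the stacked
(Re, Im) residuals weighted by 1/|Z| — modulus weighting is the standard
choice when |Z| spans decades. MINPACK manages its own damping schedule,
so the damping-parameter knobs of other LM implementations have no direct
equivalent; on these smooth 3–4 parameter problems the optimizer's path
is immaterial to the minimum reached. Reported per-parameter errors are
relative standard errors from the LM covariance; non-convergence is
flagged on the result, never raised. Note the across-animal *spread* of
fitted components and the per-fit *uncertainty* are different statistics;
both are available (the latter on every fit, the former by fitting
several spectra).

**Current and charge.** At pulson onset the uncharged C₁ shorts R₂, so
the onset current is V/R₁; within a pulson the current decays toward
V/(R₁+R₂) with τ = C₁R₁R₂/(R₁+R₂). Charge per pulse integrates this
transient analytically segment by segment, carrying the capacitor voltage
across pulson gaps (discharge through R₂, source open). In the C₁ → ∞
limit this reduces to V/R₁ × on-time, linear in duty cycle — the
closed-form oracle used in tests. Charge is monotone in duty cycle and
pulse width, which is what makes duty the controller's charge proxy.

## Plant (`plant`)

The dose-response surface is a separable power law with reference
exponents γf = 1.2, γd = 0.8, γpw = 0.5 — chosen once so that (i) the
maximum-setting anchor gives exactly 13.0% at (20 Hz, 100%, 512 µs), (ii)
low settings (≤ 5 Hz, 12.5% duty) stay below 2% of baseline, and (iii)
the response is strictly monotone in every parameter. Only the two
anchors and monotonicity are constrained by observation; the functional
form and exponents are modelling choices, exposed in `PlantConfig`. The
pulse-width exponent is the least constrained of the three (open-loop
data exists at only two widths).

Dynamics are first-order: the drop relaxes toward its target with
τ_on = 3 s while stimulating and toward zero with τ_off = 8 s at rest —
qualitative transient shapes, no measured time constants exist. HRV is
independent Gaussian noise per 5-s window (default 0.5 bpm on an 80 bpm
baseline, i.e. ~0.6% of baseline), seeded; with these defaults the mean
rest-phase window deviation stays below even the tighter (divisor-10)
bradycardia threshold, as the plant tests verify. `tachy_offset`
(default 0) shifts the whole surface to let users emulate fulcrum
crossing into tachycardia; it is synthetic — no tachycardic calibration
data exists.

**Scenario presets.** `reference`/`reference_noisy` keep A_max = 13.
`open_incision` and `closed_incision` rescale A_max by
(512/1024)^γpw so the steady response at the adverse initialization
(20 Hz, 100%, 1024 µs) equals the printed first-epoch reductions of 10%
and 6% respectively.

## Controller (`controller`)

Classification uses a single trip level. The bradycardia threshold is the
running maximum observed drop divided by 5 (or 10); the steady band
defaults to 2.5% (valid 2–4%). The effective trip is
min(threshold, band) once a response has been observed, the band alone
before. Rationale: the threshold exists to sit above natural HR
variation, and with the divisor-10 option it tightens the target; but a
threshold *looser* than the design band would let the controller declare
victory outside the band it is specified to reach (with this plant the
adverse-init maximum response is ~18%, putting the divisor-5 threshold at
3.7% — above the band), and would leave the steady-state declaration
(which is band-based) unreachable. Tying the trip to the band's floor
keeps the two rules consistent and yields final drops ≤ 2.5% within ≤ 7
updates from the adverse start, matching the behaviour the system is
designed for.

De-escalation is duty-first: duty steps down its grid
(100 → 50 → 25 → 12.5), then frequency (20 → 15 → 10 → 5 → 2 → 1), one
parameter per rest phase, never off-grid. The exact branch structure of
the original state machine is not public; this tree is one consistent
realization and is config-swappable. Tachycardia inverts the most recent
down-step, saturating at the ceilings. The active-phase response is the
*minimum* window HR (worst-case bradycardia, matching the visible dips of
transient recordings; mean aggregation by config). Steady state needs 2
consecutive in-band responses (one noisy lucky window should not end a
run); hold cycles do not count as parameter updates. Pulse width is held
fixed per run (1024 µs default): closed-loop recordings vary only duty
and frequency.

## Loop (`loop`)

Epochs are 14 s ON + 66 s OFF = 80 s = 16 windows, active phase in
windows 0–2 (ON time rounded up to the window grid). Every run prepends
a 30 s rest period so epoch 0 has a baseline; each later baseline is the
mean of the two final rest windows of the preceding epoch, verifiable
from the record alone. `full_stack` mode re-synthesizes each epoch's HR
trajectory as a stepped profile padded by one window on each side (edge
transients and the first R-R interval fall outside the scored region),
decodes it through the DSP chain, and feeds the decoded windows to the
controller; on noise-free runs this reproduces the `direct_hr` action
sequence exactly, which is the end-to-end consistency test. The
manual-intervention hook of a supervised experiment becomes an abort
predicate (default: drop > 30% terminates with status `aborted`).
RunRecords are JSON with a checked schema version; NaN windows round-trip
as null.

## Trend statistics (`trend_stats`)

S = Σ_{i<j} sign(x_j − x_i); variance with the standard tie correction
n(n−1)(2n+5)/18 − Σt(t−1)(2t+5)/18. The alternative is one-sided
*downward* (the controller should shrink successive drops), so the
p-value is the lower tail P(S ≤ S_obs), normal-approximated as
Φ((S+1)/√var) (+1 continuity correction for a lower tail on the
even-spaced support of S). Significance requires S < 0 *and* p < α
(default 0.05). Run sequences are short (n ≈ 5–10), where the normal
approximation is rough, so an exact permutation null is used when
feasible: full enumeration of all n! orderings for n ≤ 8 (valid under
ties), and an inversion-count recursion (S = T − 2·inversions,
T = n(n−1)/2) for tie-free n ≤ 10. Exact and normal p-values are both
reported; the exact one is primary when available, and the two agree
within 0.03 on tie-free sequences of these lengths (property-tested).
Drop magnitudes are the per-epoch responses clipped at zero, in epoch
order. Sen's slope, seasonal variants and multiple-testing correction
across runs are out of scope.

## Problem sizes and determinism

The acceptance script and the test suite run everything at full scale —
closed-loop runs terminate in ≤ ~10 epochs on these plants, the sensing
benchmark uses the complete 700 s × 200 Hz trace, EIS uses the default
40-point grid — in a few seconds total on one CPU; nothing is
down-sampled. Every stochastic path (generator noise, plant HRV, spectrum
noise, cohort seeding) flows from explicit integer seeds; the
8-run cohort derives per-run seeds from a single base seed, and identical
seeds reproduce records byte-for-byte.

## Known limitations

* The plant is phenomenological: no baroreflex, autonomic balance,
  respiration or anesthesia-depth mechanisms; calibration rests on two
  printed anchors plus monotone trends.
* The controller tree is one consistent realization of a state machine
  whose exact transitions are not public.
* The synthetic ECG's noise realism bounds what the 0.50%-error benchmark
  can claim about recorded signals (see `ecg_synth` above).
* Electrode electrochemistry (Faradaic limits, charge-density safety) and
  the discharge phase of charge balancing are not modelled.
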