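# Methods

This note documents the models behind `oxyloop`, the defaults and why they
were chosen, the numerical conventions, and what the simulations can and
cannot say about real patients.

## The control law

The device is modeled as a sampled-data, fixed-step (bang-bang-with-dead-band)
controller. Every `sample_period` (3 s) it consumes one SpO₂ reading and
applies exactly one of three actions:

* reading > `target_high` and ≥ `decrease_interval` (2 s) since the last
  closing adjustment → flow −= `decrease_step` (0.5 L/min);
* reading < `target_low` and ≥ `increase_interval` (5 s) since the last
  opening adjustment → flow += `increase_step` (2.0 L/min);
* otherwise hold.

The two rate gates are independent: an opening adjustment never delays a
closing one and vice versa. The commanded flow is clamped to
[`flow_min`, `flow_max`] = [0, 30] L/min and then rounded to the valve
resolution `flow_quantum` = 0.1 L/min (nearest, ties away from zero).
"Above/below the target" is interpreted as outside the closed band
[`target_low`, `target_high`]: a single set-point would chatter at every
sample, while a dead band matches the goal of *maintaining* a saturation
range. The asymmetric steps encode clinical asymmetry of risk — hypoxemia
is corrected aggressively (+2 L/min), hyperoxia unwound gently (−0.5 L/min).

Since the 2-s closing gate is shorter than the 3-s sampling period, closing
can fire at every sample while the reading stays above band; opening fires
at most at every other sample. The stated step/interval pairs could also be
read as continuous ramp rates (0.25 and 0.4 L/min per s); the discrete-step
reading is implemented because it makes each adjustment an observable,
testable event with the stated magnitude.

Sessions start with the valve closed (flow = `flow_min`); the first
adjustment is never rate-limited. SpO₂ readings outside [0, 100] % are
classed as probe-signal faults, not physiology: the flow is held, the event
is counted and logged, and the session continues. The audio alarm is a
separate flag tripped at clinician-set thresholds `alarm_low`/`alarm_high`;
the defaults place them 3 % outside the band, but they are mandatory config
fields because in use they are a clinical judgment.

## The virtual patient

The plant is deliberately minimal — one oxygen store, one algebraic gas
exchange stage — because the controller operates on minutes-scale SpO₂
trends and needs nothing finer.

**Oxygen pathway.** Flow → FiO₂ is linear with slope 0.03 per L/min above
room air (0.21), capped at 0.90: the standard bedside approximation for a
nasal cannula, whose delivered fraction saturates as inspiratory flow
outstrips the device. The alveolar gas equation
P_AO₂ = 713·FiO₂ − 1.25·PaCO₂ and a patient-constant baseline A–a gradient
give the equilibrium arterial tension; PaO₂ relaxes toward it first-order
with τ = 60 s, the simplest dynamics giving realistic minutes-scale
equilibration after a flow change. One exponential update per 3-s step is
exact for this ODE, so no sub-stepping is needed. The equilibrium tension is
floored at 1 mmHg so extreme configurations cannot produce nonpositive
tensions.

**Saturation.** SpO₂ = 100·(23400/(PaO₂³ + 150·PaO₂) + 1)⁻¹ (Severinghaus).
It is strictly monotone, accurate in the clinically relevant 80–100 % band,
and cheap to invert numerically (bisection on [1, 700] mmHg to 10⁻⁶), which
initialization from admission SpO₂ requires. Temperature, pH and 2,3-DPG
shifts of the curve are out of scope.

**CO₂ and pH.** Hypercapnic patients carry a retention mechanism: PaCO₂
drifts up at `co2_retention_rate` (0.5 mmHg/min) per % SpO₂ above
`retention_threshold` (94 %), the minimal linear stand-in for hyperoxic
loss of hypoxic drive, and recovers toward its baseline at the symmetric
rate below the threshold (never undershooting baseline). Purely hypoxemic
patients have constant PaCO₂. pH follows Henderson–Hasselbalch with
patient-constant bicarbonate — over a 4-hour session there is no renal
compensation, so pH moves only with PaCO₂. The drift uses the saturation at
the start of each step (the exposure during the interval).

**Measurement and disturbances.** The oximeter adds Gaussian noise
(SD 0.5 %, a modern finger probe) and clips to [0, 100]. Disturbance onsets
are Poisson (2/h); each raises the A–a gradient by 15 mmHg for 120 s,
standing in for coughing, secretions and position changes. A new onset
during an active disturbance restarts the clock rather than stacking.

## The synthetic cohort

The generator emulates the admission statistics of a small hospitalized ARF
cohort: 13 hypercapnic + 10 purely hypoxemic patients, room-air admission
PaO₂ ~ N(52.73, 7.65²) truncated to (30, 59.9) mmHg, and phenotype-specific
PaCO₂ — N(55, 8²) on (45.1, 90) for hypercapnic, N(38, 4²) on (25, 45) for
hypoxemic — whose mixture reproduces a pooled PaCO₂ near 48.5 mmHg with a
large spread. Admission SpO₂ is derived from PaO₂ through the dissociation
curve (at these tensions the generated cohort mean is ≈ 84 %), and the
baseline A–a gradient from the alveolar gas equation at FiO₂ 0.21. PaCO₂ is
drawn first and the PaO₂ upper truncation is additionally capped 1 mmHg
below the alveolar tension, so every patient has a nonnegative gradient;
the cap binds only for PaCO₂ ≳ 72 mmHg, i.e. rarely. Bicarbonate encodes
chronic renal compensation, 24 + 0.35·(PaCO₂ − 40) mmol/L for hypercapnic
patients (≈ 3.5 mmol/L per 10 mmHg, giving admission pH ≈ 7.33–7.36) and
24 for hypoxemic ones. Each patient receives an independent seed spawned
from the cohort seed; session streams can additionally be derived from a
master seed so that permuting the cohort never changes a trajectory.

## Session protocol and conventions

A session runs 4 h (14400 s) at the controller cadence: measure → adjust →
advance per 3-s step. The record at t = 0 is taken before the first
adjustment, so a session holds duration/dt + 1 records; the flow column of
each record is the flow being delivered at the sampling instant
(pre-adjustment). Arterial blood gases are snapshotted at exactly 3600 s and
10800 s as the *true* state — a simulated blood draw, the reference
measurement — not the noisy oximeter value. Time-in-range statistics are
fractions of recorded samples (the device's native cadence), not
interpolated wall-clock time, and use the *measured* SpO₂, since that is
what a recording device stores. Excursion thresholds ≥ 93 % / ≤ 87 % are
reported for both phenotypes although they coincide with band edges only
for the hypercapnic band. Cohort summary SDs use the n−1 convention; groups
of one report SD as NaN, never 0. The automatic correlation-method choice
screens both margins with a Kolmogorov–Smirnov normality test at α = 0.05
(low-powered at n ≈ 23, which is why the method is also directly
selectable).

## Closed-loop behavior and known limitations

A structural property of this plant–controller pair is worth stating
explicitly, because the test suite measures it. One 0.5 L/min closing step
moves the equilibrium PaO₂ by 713 × 0.03 × 0.5 ≈ 10.7 mmHg, while the
hypercapnic 88–92 % band spans only ≈ 9 mmHg of PaO₂ on the dissociation
curve. Combined with the 60-s plant lag — the measured SpO₂ stays above the
band for several samples after the flow has already crossed the in-band
window — the down-titration frequently walks past every in-band flow, and
part of the cohort settles into a slow hunt (period ~2–3 min) around the
band instead of a hold. Under the reference conditions this yields a mean
time-in-band of ≈ 82–85 % for hypercapnic and ≈ 91–94 % for hypoxemic
sessions (whose band is ≈ 22 mmHg wide in PaO₂), and worst-case excursions
of ≈ 1–1.25 min dominated by the initial titration transient from room air
at closed valve. Real patients with severe gas-exchange impairment have much
larger A–a gradients and flatter, shunt-dominated flow responses than the
alveolar-equation plant used here, which widens the effective in-band flow
window relative to the valve step; the simulated in-band percentages are
therefore a conservative floor, not an estimate, of bedside performance.
Passing tests show the algorithm is implemented to its stated constants and
is safe (no CO₂ retention above baseline + 1 mmHg, prompt recovery from
desaturation events); they do not validate the plant against patient data.

Other limitations: no ventilation–perfusion or hypoxic-drive mechanism
(retention is a linear surrogate); no disease-specific phenotypes; no
metabolic acid–base dynamics; a single well-mixed oxygen compartment; the
flow→FiO₂ line ignores breathing pattern. All dynamics parameters are
config-overridable per patient or cohort.
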