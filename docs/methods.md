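# Methods

`frailsense` implements the signal-processing core of a wearable
remote-monitoring platform for frail and pre-frail elderly users: a
lower-back accelerometric fall detector with a distributed two-stage
architecture, a smart-vest channel for exercise repetition counting and
metabolic estimation, a capacitive respiratory channel, and the
smartwatch-side alert logic.  This note documents the models, the
parameters that matter, the synthetic-data design, and the numerical
choices.

## Sensing model and conventions

Both devices sample triaxial acceleration at 40 Hz.  The device x-axis is
aligned with the trunk longitudinal axis when the wearer stands, so a
standing subject reads a gravity projection of ≈9.81 m/s² on x and a
lying subject ≈0.  The respiratory channel is a dimensionless amplitude
proportional to thoraco-abdominal expansion; rising amplitude is
inspiration.  The transduction hardware (oscillator, electrodes) is not
modeled.

## Personalization parameters

All detector thresholds ship with factory defaults and are
per-subject-tunable through the YAML config (`device:` section):

| parameter | default | units | role |
|---|---|---|---|
| vertical posture threshold | 6.5 | m/s² | trunk-axis gravity projection above which posture is vertical |
| horizontal posture threshold | 2.5 | m/s² | projection below which posture is horizontal |
| fall energy threshold | 0.079 | m²/s⁴ | stage-1 trigger and stage-2 energy criterion |
| movement activity energy threshold | 0.1490 | m²/s⁴ | floor from which the cycle-amplitude hysteresis is derived |
| resting energy threshold | 0.0306 | m²/s⁴ | epochs/cycles below this are rest |
| ascending / descending displacement threshold | +0.1 / −0.12 | m | climb tagging / fall displacement criterion |
| intense motion artifact threshold | 3.7 | m/s² | respiratory gating level on \|‖a‖−g\| |

Anthropometric parameters (weight, birth date, gender, height, thorax
perimeter) have **no defaults**; metabolic estimation refuses to run
without a weight.  Alert timings (30 s fall prompt, 3 s SOS hold, 5 s
countdown) are configurable because the deployed values are not public;
the 3 s hold is the documented device behaviour.

## Stage 1 — impact detection

The impact statistic is the centred moving variance of ‖a‖ over a 0.5 s
(21-sample) window, shrinking at stream edges.  Variance of an
acceleration has exactly the units of the fall-energy threshold
(m²/s⁴), removes DC (so the statistic is invariant to adding a constant
vector), and a 0.5 s window spans an impact transient.  One impact is
emitted per local maximum above the threshold, with a 4 s refractory
period keeping the higher-energy candidate, so one fall with bounces
yields one excerpt.  Each excerpt spans 2 s before to 2 s after the
impact sample (161 samples); excerpts clipped by a stream boundary are
flagged truncated.  Excerpts serialize into 20-byte transfer blocks
(int16 fixed point at ±16 g, 40-byte header), emulating the BLE GATT
payload framing of the original device.

## Stage 2 — fall classification

A candidate is a fall iff all of:

1. impact energy ≥ fall energy threshold;
2. vertical posture over the first second of the excerpt;
3. horizontal posture over the last second;
4. vertical displacement ≤ −0.12 m (downward).

Posture is the absolute mean trunk-axis projection; values between the
two thresholds take the nearer class, the exact midpoint resolving to
vertical so the pre-impact check leans against false alarms.  Post-impact
immobility is deliberately not a criterion: attempts to stand up would
otherwise turn real falls into misses.

**Vertical displacement.**  ‖a‖ − g is an orientation-free surrogate of
the trunk's vertical acceleration (the magnitude is invariant to the
rotation a fall induces).  Double integration amplifies slow baseline
error as 1/ω², so a full-window integral is hopeless under realistic
baseline wander; instead the integral is restricted to the *event
support* — samples with |‖a‖ − g| > 2 m/s² (well above sway, far below
any impact), dilated by 0.2 s — after subtracting a linear baseline
fitted on the 0.6 s flanks either side.  The wearer is taken as
quasi-static at the support start (v = 0), and the signed extreme
excursion of the doubly trapezoid-integrated trace is returned.  Windows
with no gate exceedance contain no measurable vertical transition and
return 0.  On a noiseless free-fall profile the estimate matches the
discrete double integral to ~1%; at the protocol noise level fall
estimates stay within ±0.15 m of truth and pure noise produces exactly 0.

## Sawtooth parameterization (exercise and respiration)

Repetitions and breaths are both rise/fall cycles of a quasi-triangular
waveform.  The shared engine band-passes the signal (0.05–3.5 Hz for
accelerometry, 0.05–1.5 Hz for respiration), finds alternating extrema
with an amplitude hysteresis, snaps each extremum back to the raw signal
(so cycle timing is not biased by the filter), and assembles
trough→peak→trough cycles.  A pending trailing trough that follows a
committed peak is flushed at the stream boundary — without this the last
repetition of every finite recording is lost.

The accelerometric hysteresis derives from the movement threshold: a
triangle of peak-to-trough A has variance A²/12, so the floor is
`sqrt(12 × 0.1490) ≈ 1.34 m/s²`.  The respiratory hysteresis is 30% of
the 5th–95th percentile excursion, making segmentation invariant under
positive rescaling of the arbitrary-unit channel.  Cycles shorter than
1 s are rejected on the respiratory channel (60 breaths/min ceiling).

Counting selects the dominant axis (largest 0.2–3 Hz band power), applies
exercise-specific period bounds (0.5–2× the nominal period of the
user-selected exercise) and drops cycles whose span never shows
movement-level energy on the conditioned trace.  Activity identification
is nearest-signature matching on (dominant axis, median period, median
amplitude, rise asymmetry) against signatures measured by the same
pipeline on noiseless templates, and maps each exercise to its body
region (total / upper / lower body).

## Metabolic estimation

Activity counts are the mean rectified band-passed ‖a‖ per 10 s epoch
(the shortest epoch spanning several cycles of the slowest exercises).
Counts map linearly to MET, anchored at 1 MET at rest and 3.5 MET at the
reference walking amplitude; epochs with energy below the resting
threshold floor at 1 MET.  kcal/min = MET × 3.5 × weight / 200 (the
standard 3.5 ml O₂/kg/min equivalence); cumulative expenditure is the
time-integral of the piecewise-constant rate, hence exactly additive over
epoch-aligned concatenation.  Epochs whose vertical excursion exceeds
+0.1 m are tagged ascending.  The MET mapping is this package's own
definition: the platform reports these quantities but publishes no
formula.

## Respiration

Breath cycles come from the sawtooth engine (rising flank = inspiration).
When a concurrent acceleration stream is supplied, intervals with
|‖a‖ − g| > 3.7 m/s² gate every overlapping cycle; gated cycles are
flagged and never contribute to any rate estimate.  Rates are
60 / mean cycle period over sliding windows of non-gated cycles.

## Alert logic

The state machine (idle → fall_prompt → alert_sent/cancelled; idle →
sos_countdown → alert_sent/cancelled) takes time only through explicit
`now`/`tick` arguments, so behaviour is deterministic and the safety
property — `alert_sent` is reachable only through a confirmed fall, an
expired prompt, or a completed ≥3 s SOS hold plus countdown — is checked
by exhaustive enumeration of action sequences in the tests.  An
unanswered fall prompt always escalates to an automatic alert.  The event
log is append-only and chronological, with typed records for falls,
alerts, activity reports, breathing summaries and passthrough types
(heart rate, reminders).

## Synthetic-data design

No public recordings exist for this platform, so the generator module
reproduces the laboratory validation protocol with ground truth:

* **Falls** — quiescent standing; a sub-gravity descent pulse
  accumulating a 0.45–0.55 m drop (knees / chair / bed variants); an
  impact half-sine whose peak is drawn from 30–60 m/s²; trunk rotation
  from vertical to horizontal.  The device signal is the world-frame
  specific force rotated into the device frame, so ‖a‖ = |g + z̈| holds
  exactly.  The sampled impact pulse is rescaled so its discrete
  trapezoidal integral exactly cancels the descent velocity; without
  this the few-sample pulse leaves a spurious residual velocity.
* **Fall-free ADLs** — gait harmonics of bounded amplitude (walking,
  stairs) and slow posture transients (sitting: 0.40 m over 3 s;
  bending: 60° trunk tilt with a 0.25 m dip).  None satisfies the fall
  conjunction: energies stay below the stage-1 threshold and postures
  remain vertical.
* **Exercises** — asymmetric-triangle oscillations on a per-kind
  dominant axis.  Cadences (1.5–5 s periods for the 15 static exercises,
  100 steps/min walking, 60 rpm cycling) and amplitudes (2.4–3.2 m/s²
  peak-to-trough) are stated assumptions, not published values, chosen
  in the range of slow maintenance exercise and — consistent with the
  platform's validated 100% repetition precision — comfortably above the
  1.34 m/s² hysteresis floor.
* **Breathing** — raised-cosine inspiration (40% of the period) and
  expiration.  Cycle boundaries are exact floats evaluated on a single
  global 40 Hz grid including the closing boundary sample, so integer
  cycle periods are recovered grid-exactly.
* **Noise** — additive Gaussian noise band-limited to 0.2 Hz (white
  noise low-passed and rescaled to the requested per-sample SD).  At the
  sacrum/thorax the dominant perturbation is slow postural and
  soft-tissue sway; the accelerometer's own wide-band noise (<0.01 m/s²)
  is negligible against the movement signals and is not modeled.  The
  cut-off was fixed by a design sweep: at 0.2 Hz the noise's 0.5 s
  windowed variance stays an order of magnitude below the fall-energy
  threshold, which is the regime in which a single energy threshold can
  separate gait from impacts at all.
* **Protocol** — per subject and repetition, an interleaved sequence of
  the five fall-free and three fall activities (8 single-activity
  streams), with per-subject anthropometrics drawn from the volunteer
  statistics (age 38 ± 6.2 y, height 175 ± 4.8 cm, weight
  75.7 ± 5.3 kg).

What passing tests on these signals show — and what they do not: the
generator exercises every feature the detectors use (energy transients,
posture transitions, downward displacement, cycle structure, artifact
bursts) under controlled noise, so the tests demonstrate internal
correctness and noise margins of the algorithms.  They do not
demonstrate performance on real human kinematics: real falls have
soft-tissue oscillation, pre-impact flailing and variable orientations;
real exercise is less periodic; real respiratory baselines drift.  The
replication figures are a consistency check against the platform's
laboratory results, not an independent clinical validation.

## Numerical choices and degenerate inputs

* All filters are Butterworth order 2, applied zero-phase
  (`sosfiltfilt`); integration is trapezoidal.
* Noise generation pads the white input and trims after filtering, so
  filter edge transients never enter a stream; the realized SD is
  normalized exactly per stream.
* Posture ties at the 4.5 m/s² midpoint resolve to vertical; truncated
  excerpts are classified on the available criteria and flagged
  low-confidence; empty streams, sub-0.5 s posture segments, <2 s
  exercise streams and <10 s respiratory signals raise typed errors.
* Replication problem sizes: 3×3 protocol sequences (72 streams of
  10–12 s), 6 repetitions per static exercise, 60 s locomotion runs
  averaged over 20 seeds, and a 6→30 breaths/min ramp of 3 cycles per
  step — the sizes of the original laboratory campaign.

## Known limitations

* The impact statistic and the stage-2 rule are reconstructions
  constrained to the published parameter set; the original references
  describing the on-device algorithms are not public, so the exact
  statistic may differ.  Both are isolated behind single functions.
* Trunk-axis calibration is assumed perfect; real deployments would need
  an orientation calibration step.
* The displacement estimator returns 0 for slow transitions that never
  exceed the 2 m/s² gate (e.g. slow sitting); this is intentional for
  fall discrimination but means the ascending tag only fires for
  vigorous climbs.
* The MET mapping is linear in activity counts with two anchor points;
  it is a reporting convention, not a calibrated energy-expenditure
  model.
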