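# Methods

## The model

### Virtual subject

The subject is a passive single-compartment respiratory system driven by
the ventilator's airway pressure and its own respiratory muscles:

    flow = (Paw − PEEP − V/C + Pmus) / R,      V' = flow,

with volume `V` (L) measured above the end-expiratory equilibrium at PEEP,
inspiratory flow positive, airway resistance `R` (cmH2O·s/L) and
respiratory-system compliance `C` (L/cmH2O). `Pmus ≥ 0` (cmH2O) is the
muscle pressure; it *lowers* alveolar, pleural and oesophageal pressure.
Integration is explicit fixed-step at the sampling interval (default
fs = 100 Hz; the acquisition rate of the original recordings is not
documented, so it is a free configuration parameter). Against a closed
valve (hold manoeuvre, volume-control pause) flow is forced to zero,
volume is frozen, and the recorded airway pressure equals the alveolar
pressure `PEEP + V/C − Pmus` — during an end-expiratory hold Paw
therefore drops by exactly the instantaneous muscle pressure, which is
the waveform signature the IE induction and the classifier both rely on.

Each inspiratory effort is a half-sine rise to its peak over the neural
inspiratory time `Ti_n`, followed by exponential relaxation with time
constant `Ti_n/2`, truncated at `3·Ti_n`. Effort onsets form an
open-loop renewal process: intervals are Gaussian with mean
`60/(neural_RR·sedation_factor)` and standard deviation `rr_jitter_sd`
(floor 0.5 s). Sedation scales both the effort amplitude and the
intrinsic rate. There is **no chemoreflex**: effort timing never reacts
to delivered volume, which is the single most important difference from a
live animal (see *Limitations*).

The oesophageal pressure channel is
`Peso = baseline + E_cw·V − Pmus + a_c·sin(2π f_c t)` with a chest-wall
elastance share `E_cw` (default 5 cmH2O/L), a cardiogenic oscillation
(default 0.5 cmH2O amplitude at 1.5 Hz, i.e. 1 cmH2O peak-to-peak —
deliberately below the 2 cmH2O effort-dip threshold), and baseline
5 cmH2O. A pleural-pressure channel is emitted as Peso without the
cardiac artifact.

Default mechanics, `R = 10 cmH2O·s/L` and `C = 0.030 L/cmH2O`, are
plausible for a 40–58 kg pig after experimental lung injury ventilated at
6 mL/kg; no subject-specific values are documented, so they are stated
here as the package's reference subject, not a fit.

**Effort calibration.** The study protocol titrates sedation to an
airway-occlusion pressure P0.1 ≈ 2.5 cmH2O. With the half-sine rise,
P0.1 = Pmax·sin(π·0.1/(2·Ti_n)); the default phenotype uses
`Ti_n = 0.4 s`, `Pmax = 6.5 cmH2O` (P0.1 = 2.49 cmH2O). The short neural
inspiratory time (duty cycle ≈ 0.22 at the tachypnoeic intrinsic rate of
injured pigs) also matters mechanistically: during a ramp-prolonged
breath the effort must relax while the pressure is still rising for the
second flow hump of a stacked breath to appear. The hold-titration pilot
scenario uses a deliberately different phenotype (`Ti_n = 0.55 s`,
`Pmax = 12`, intrinsic RR 36/min): that experiment preceded the drive
titration, and its published behaviour — the animal still inhaling when a
hold of one inspiratory time ended — requires long, strong efforts.

**The subject leads the ventilator.** In every scenario the intrinsic
effort rate is set 10% above the set ventilator rate. Consequently,
absent modifications, every breath is subject-triggered (the flow-trigger
fires before the timed deadline), which is what makes the synchrony arm's
AIX exactly zero and lets the loop re-entrain within one or two breaths
after a timing perturbation. The bench lung-simulator module is run the
same way even though its nominal setting equals the ventilator rate:
two mathematically identical clocks with zero jitter would stay
permanently de-entrained after any perturbation, an artifact no physical
bench shows.

### Ventilator

A phase machine with states INSPIRATION, EXPIRATION, HOLD_EXP, HOLD_INSP.
Pressure modes (BIPAP, pressure assist-control) regulate Paw to a linear
ramp from PEEP to Pinsp over the rise time, then a plateau, through a
first-order servo with a 20 ms time constant (ideal regulation;
servo dynamics of real machines are not modelled). IPPV delivers a
constant inspiratory flow until the set tidal volume is reached, then
holds an inspiratory pause until time-cycling. Expiration is passive
through the airway resistance. Subject triggering uses a flow threshold
(default 3 L/min) active during expiration after a 300 ms refractory
period. Timed breaths fire on a deadline one period after the cycle
start; a deadline that elapses while the valves are closed produces the
overdue breath `hold_rearm` seconds (default 0.35 s; 0 for
operator-released holds) after the hold ends — the "delivery immediately
after the hold" behaviour that distinguishes sub-threshold holds from
IE-inducing ones.

### Induction controller

* **IE** — an end-expiratory hold is armed for the target cycle; the
  valves close on the subject's next trigger-level flow excursion (or at
  the timed deadline) and stay closed for `k_hold` × the reference time
  (default 1.5 × inspiratory time; the reference is selectable because at
  I:E = 1:1 the inspiratory- and expiratory-time readings coincide, which
  likely explains the two phrasings in the source protocol).
* **AT** — the preceding cycle's timed period is shortened to
  `60/(RR·1.5)` with triggering disarmed, so a mandatory breath with a
  0.5 s inspiratory time fires ~0.4–0.5 s before the subject's expected
  effort.
* **DT** — the pressure ramp is prolonged for three consecutive cycles;
  default override 2 s where the inspiratory time allows it, else 0.9 ×
  the inspiratory time. The subject's effort (which triggered the breath)
  relaxes mid-ramp, flow falls, and completion of the ramp produces the
  second flow hump.

Events are drawn per type at `fraction_per_type` (default 5%) of the
expected breath count — computed at the *realized* (subject-led) rate —
by block allocation: random event order, a mandatory `min_gap` (default 2
cycles) between events, spare cycles distributed multinomially. Counts
are exact, placements reproducible under the seed, and the 30%
dose-response arm remains feasible. The first three cycles stay pristine
for classification context.

Ground truth records, per machine cycle, the start time, origin
(timed/triggered) and the scheduled modification. For IE events the truth
label is derived from simulator internals: the cycle is IE only if an
effort actually fell into the hold and no inspiration started until well
after the effort released; a deliberately sub-threshold hold therefore
carries truth NORMAL even though a hold was applied.

## The classifier

Works from waveforms only (flow, Paw, Peso), deterministically.

1. **Segmentation** — inspirations are runs of flow above θ_flow
   (0.05 L/s) sustained ≥ 50 ms; runs shorter than 150 ms are artifacts.
   Two runs separated by < 300 ms with expired volume < 25% of the
   preceding inspired volume are merged *only if* Paw in the gap is still
   ≥ 2 cmH2O above PEEP (the machine is mid-insufflation): that keeps a
   stacked "M" inside one inspiration while a fresh breath after a real
   expiration stays a new cycle. Cycles tile the record; a cycle is a
   *machine* cycle if Paw rises ≥ 2 cmH2O above the PEEP estimate (10th
   percentile of Paw).
2. **Effort detection** — dips of Peso ≥ θ_dip (2 cmH2O) below a rolling
   5 s median baseline, lasting ≥ 100 ms. The threshold sits above the
   cardiac artifact's peak-to-peak amplitude; the long window keeps a
   deep one-second dip from dragging its own baseline down.
3. **Effort reward** — an effort is rewarded if any inspiration starts
   within [dip start − 0.5 s, dip end + 0.5 s], or if it begins during an
   ongoing inspiration (it rides the insufflation). Unrewarded efforts
   mark their enclosing cycle **IE**.
4. **AT** — a machine cycle with no effort-dip interval intersecting
   [onset − 0.3 s, onset + 0.35 s] is auto-triggered, *unless* the
   preceding gap contains an occlusion signature (≥ 0.25 s of zero flow
   with Paw ≥ 1.5 cmH2O off PEEP): a breath resuming ventilation after a
   hold is not AT.
5. **DT** — two flow peaks inside one machine inspiration (prominence
   ≥ 10% of the cycle's peak flow, ≥ 100 ms apart, interior maxima only)
   with the inter-peak valley occurring while Paw is still below 90% of
   its rise; or two machine inspirations whose gap is shorter than half
   the running-mean inspiratory time (last 10 machine cycles) with
   expired volume < 25% of the preceding inspired volume (both cycles
   flagged). The Paw condition separates ramp-prolongation stacking from
   an effort landing on an established plateau.
6. Label priority DT > IE > AT; anything else is NORMAL (or OTHER for an
   effort-only excursion). AIX and per-type incidences are fractions of
   all cycles; every cycle of a DT cluster counts once. Group summaries
   report median and [Q1–Q3] with linear interpolation; no hypothesis
   testing.

The reference procedure was visual inspection by a trained physician; all
numeric thresholds above quantify that judgement and are configurable in
`ClassifierParams`. The defaults were chosen from the closed-loop timing
analysis of the simulator (effort-dip onset lags effort onset by
~0.1 s; a triggered breath's dip begins ~0.1–0.3 s *after* the machine
onset because the trigger reacts at a fraction of the dip threshold).

## Numerical choices and edge cases

* Explicit Euler at dt = 1/fs; the passive step response matches the
  closed-form exponential to < 1% once dt ≲ 1 ms (test-verified); at the
  default 10 ms the deviation is a few percent, immaterial next to the
  classifier's thresholds.
* Pressures are continuous through phase changes via the 20 ms servo.
* Ties: a trigger-level flow in the same sample as a timed deadline goes
  to the hold/trigger branch before the deadline branch.
* Degenerate inputs raise: non-finite mechanics inputs, dt outside
  (0, 20 ms], ramp ≥ inspiratory time, IPPV volume not deliverable within
  the inspiratory time, infeasible schedule packing.
* `effort_amplitude_Pmax = 0` gives a passive subject; all cycles are
  timed and the classifier labels them AT by definition (a mandatory
  breath without any effort nearby) — the scenario catalogue avoids this
  by keeping the subject leading.

## What the synthetic data do and do not show

The generator reproduces the *timing logic* of induction and the
waveform signatures used for classification: Paw dips below PEEP during
occluded efforts, triggered-breath Peso dips, the M-shaped flow of
ramp-prolonged breaths, cardiac interference on Peso. It does not
reproduce chemoreflex feedback, behavioural/sigh variability,
two-compartment heterogeneity (Pendelluft), leaks, secretions or sensor
noise beyond the cardiac artifact. Passing tests therefore show that the
induction mechanisms and the rule cascade are internally consistent and
recover designed event rates under realistic timing jitter — not that
the classifier would reach the same accuracy on animal recordings.

Problem sizes: the replicate experiments run 600 s at 100 Hz (about 320
breaths each), seven seeds for the asynchrony arm; these sizes give
binomial noise on the AIX of about one percentage point, small relative
to the ±3-point design tolerance.

## Known limitations

* Open-loop effort timing makes re-entrainment after a perturbation a
  pure clock-drift process; one or two transitional breaths after a
  sub-threshold hold can carry ambiguous labels (documented residual
  disagreement of ~1% between classifier and ground truth).
* AT induction under-realizes its 5% allocation by design faithfulness:
  with a fast intrinsic rate the early mandatory breath sometimes lands
  close enough to the subject's next effort to look synchronous — the
  same shortfall the animal experiments report.
* The BIPAP implementation treats the mode as pressure assist-control
  (its behaviour at the high pressure level during spontaneous breaths is
  simplified to time-cycled release with superimposed subject flow).
* Reverse triggering, delayed triggering, premature cycling and flow
  starvation are out of scope.
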