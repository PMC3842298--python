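# Methods

## Scope and level of description

`whiskloop` models the shortest sensorimotor loop of the rat whisking
system — whisker, follicle afferents, trigeminal second-order cells, facial
motoneurons, mystacial muscles — as interacting state machines under one
deterministic discrete-event scheduler. The aim is behavioural fidelity at
the kinematic level (whisk-cycle timing, protraction peaks, touch-induced
pump signatures), not biophysical fidelity at the membrane level: neurons
are threshold units, muscles are calcium-gated force generators, whiskers
are rigid levers. Everything a run produces is a deterministic function of
(configuration, seed).

## Execution semantics

Time is an integer microsecond counter. Events carry (due time, insertion
sequence) and equal-time events dispatch in posting order, which makes
traces byte-reproducible; the statechart dialect is flat states, guarded
transitions (condition connectors become guard-ordered transition lists),
entry-armed timeouts (re-entering a state cancels its stale timeouts) and
run-to-completion actions. The plant integrates on a fixed 0.5 ms grid
interleaved with the event queue: all events up to a step boundary are
dispatched, muscle forces are evaluated, the whisker array advances one
semi-implicit Euler step, and the transducer converts the new kinematic and
contact state into afferent volleys.

## Rhythm generation

Each of the three CPGs stimulates all motoneurons of its type while in
`Activate` (one volley per `cycleDuration`, `cyclesNum` volleys), then
relaxes for `silenceDuration`; the period is exactly
`cyclesNum*cycleDuration + silenceDuration = 150 ms` for all three. Their
phase offsets (extrinsic protractor 0-40 ms, intrinsic 31-81 ms, extrinsic
retractor 95-150 ms) implement the tri-phasic activation. An inhibitory
veto on a CPG *pauses* it — vetoed volleys are neither emitted nor counted,
and the stimulation budget resumes when the veto lifts — while the
following silent period is shortened so the next active period starts back
on the CPG's nominal grid. This keeps the three rhythms mutually phased
across contact cycles and is our resolution of a point the loop's verbal
description leaves open.

## Neurons

A neuron integrates weighted synaptic events in a leaky accumulator
(`tau_accum` 10 ms), fires when the accumulator crosses `threshold` from
`Rest` (or the higher `rrp_threshold` from the relative refractory period),
relays its spike `t_relay` later, and is absolutely refractory for `ARP`;
the minimum inter-spike interval is therefore `t_relay + ARP`. The leak is
what makes the mixed whisking regime well-posed: without it, sub-threshold
input accumulates without bound and "neither source alone reaches
threshold" cannot hold over a long run. Inhibitory events subtract from the
accumulator (floored at zero) and impose a configurable firing-veto window,
our stand-in for inhibitory burst kinetics that are not otherwise
constrained; vetoes register in every state, and a veto arriving while a
spike is being prepared cancels its emission.

Sensory transduction: whisking (W) cells tick with per-cell jittered
periods (~10 ms, drawn once from the seeded RNG) whenever their whisker is
in motion — in either sweep direction, because the mixed regime needs
motion-gated drive during retraction as well; contact (C) cells fire one
volley at contact onset; pressure (P) cells fire every 6 ms *while the
whisker presses the obstacle* (clamped with net protractive torque), with a
first-spike latency `4.5 + 19 r` ms increasing with the radial fraction r
of the contact point; detach (D) cells fire once when the whisker leaves
the 2 degree contact reserve. Gating pressure cells on pressing rather
than on mere touch is what terminates a pump's drive as soon as the whisker
backs off the obstacle, and it is what makes the pump's re-protraction
(and, at small r, a further pump) possible while contact is maintained.

## Muscles

Calcium jumps per motoneuron spike (normalized so a full synchronous volley
adds `dca_volley`, with a ceiling `ca_max`), decays with `tau_ca`, and
gates contraction at `ca0`. Contraction additionally requires a live
*tetanus hold*: only a volley whose within-timestamp sum reaches
`trigger_frac * dca_volley` refreshes the hold (5-10 ms). The hold is the
model's synchrony detector: an intrinsic sling shared by two whiskers
relaxes within milliseconds when one of its two motoneuron pools is
silenced, because the surviving half-volleys no longer trigger it — this is
what gives the direct I-P mechanism its short pump latency while leaving
free-air drive unaffected. Force tracks
`a_max * (1 - exp(-(Ca - ca0)/ca_sat))` through a first-order filter with
separate build-up (23 ms for intrinsic muscles — this shapes the
protraction ramp) and relaxation (4-6 ms) time constants.

Topology: a row of n whiskers has n intrinsic slings (index 0 anchors the
caudal-most whisker to the pad); sling j applies 0.75 of its force to its
caudal whisker j and 0.25 to whisker j+1, so every whisker receives one
unit of intrinsic drive except the rostral-most whisker of a seven-whisker
row, which lacks a rostral sling and receives only the 0.25 spill-over —
the source of its depressed (~74.2 vs ~80 degree) protraction peak. In
four-whisker rows a pseudo-intrinsic muscle, driven by the same whisker's
intrinsic motoneurons, stands in for the missing sling. Extrinsic muscles
act as groups (superficial protractors per row block, one superficial
retractor across all rows, deep retractors per row block); any member
pool's activity contracts the whole group.

## Plant

Rigid whiskers in a single plane: inertia 6 deg ms^2, damping 9.5 deg ms,
stiffness 1 (torques are therefore read directly in degrees of static
deflection), rest angle 70 degrees. The obstacle clamps the touching
whisker at its azimuth while net torque is protractive; release occurs the
moment net torque turns retractive, and a detach event is generated only
below `theta_obs - 2 deg`. The default obstacle stands at 74.7 degrees on
whisker A4 — mid-protraction, matching the touch angle of the benchmark
contact — at radial fraction 0.4.

## Why the three pump mechanisms differ

All three share the pressure-latency clock, so their pump delays are within
a couple of milliseconds of each other (~17 ms for E-R, ~19 ms for the
inhibitory routes, which add the tetanus-hold expiry). Their amplitudes
separate for mechanical reasons: the E-R kick fights the full protractive
drive, so the touching whisker yields only the excess of the kick over its
clamp margin (~0.6 deg) while freely-moving whiskers dip 1-2.5 deg; direct
I-P silently removes the touching whisker's own slings (~2.5-3 deg pump,
shared with its sling neighbours); indirect I-P silences every intrinsic
muscle, so non-touching whiskers fall from their ~79 degree excursion
toward rest (~9 deg) while the touching whisker, parked at the obstacle,
can only fall ~6 deg. These orderings (indirect > direct > E-R for the
touching whisker; touching+neighbours vs all-ipsilateral spread) are
emergent, not wired in.

## Analysis layer

Cycles are segmented at retraction minima of a zero-phase 40 Hz low-passed
trace (cutoff configurable, in the range used for tracked-whisker data);
protraction is trough-to-peak, the set-point the cycle-mean angle. A pump
is a local maximum (or clamp-plateau end) after contact onset followed by a
retraction of at least `delta_tip = 0.3 deg` — large enough to clear
numerical ripple, small enough to catch the weakest (E-R, high-r) pumps —
at a rate of at least 0.05 deg/ms, completed within 55 ms, and followed by
a re-protraction of at least 5 % of the retraction within 45 ms. The
terminal retraction of the cycle fails the duration cap; slow sags of the
protraction envelope fail the rate bound. A pump whose re-protraction drive
is too weak to reverse motion before phase 3 takes over (the weakly-driven
rostral-most whiskers under indirect I-P) is confirmed instead by its
descent *arrest-then-renewal* signature, which a plain terminal retraction
never shows. Detach/re-contact episodes separated by less than 50 ms are
grouped into one bout, and per-bout first pumps are the reported statistic.
A separate classifier flags the "slowed down without detectable
retraction" response. Occurrence statistics use the exact binomial tail
(scipy's exact implementation behind `binom_test`).

## Synthetic-trace fixtures

`whiskloop.fixtures.generate_fixture` emulates tracked-whisker output:
sinusoid or asymmetric-ramp cycles with configurable period, amplitude,
set-point and Gaussian noise, synthetic contact episodes, and injected
pumps of known delay/amplitude carved out of a clamped plateau so ground
truth is exactly recoverable. It reproduces the geometry of multi-whisker
pump scenes (all tracked whiskers pumping while a subset touches) for
testing the detector without the simulator. What fixtures do not emulate:
head motion, tracking dropouts, whisker bending, or amplitude/set-point
drift across cycles — detector performance on them bounds only the
segmentation/detection logic, not robustness to real video artefacts.

## Calibration

`whiskloop.calibrate.calibrate` measures the benchmark observables and
applies a fixed sequence of bounded secant refinements (intrinsic and
extrinsic-protractor gains against the two peak targets, the
pressure-latency intercept against the 17 ms pump delay, the superficial
retractor gain against the 0.6 degree touching-whisker pump), accepting a
step only if it shrinks that observable's residual. The shipped
`data/default_params.json` is the product of this tuning and all tests and
benchmark scripts run against it unchanged.

## Numerical and design choices

- Timestep 0.5 ms (fast plant pole ~1.5 ms); semi-implicit Euler.
- Clamp release decides on net instantaneous torque at zero velocity.
- Free-air benchmark statistics skip the first 200 ms start-up transient;
  pump statistics skip contacts before 250 ms.
- A two-volley start-up nudge from the run manager gives the motion-gated
  afferents motion to report; in the CPG-only regime it only perturbs the
  first (discarded) cycle.
- Sensory transduction for a subtype is skipped when its second-order pool
  has no post-synaptic targets (pure run-time saving; the populations and
  wiring are always constructed).
- Problem sizes: benchmark runs use 2 s of simulated time for free-air
  kinematics and 0.75-1 s per pump configuration, enough for 4-11 steady
  cycles per statistic.

## Known limitations

- Peak-to-trough whisking amplitude is ~13 degrees against ~10-11.5 in the
  reference kinematics (the protraction rise above rest is ~10, as
  intended); the retractor strength needed for the E-R pump deepens the
  free-air trough to ~67 degrees.
- Pumps occur in every contacted cycle, and at most one pump per cycle
  under the default timing (the re-pressing pump falls into the terminal
  retraction); the observed sub-unity pump probability and occasional
  second pump per cycle are attributed to top-down modulation, which is
  outside this loop and out of scope.
- Whisker bending, roll and elevation, pad translation as a separate
  coordinate, the contralateral pad, and learning of synaptic weights are
  not modeled.
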