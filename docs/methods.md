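# Methods

## Plant model

The simulated patient is a lumped-volume circulatory flow loop. A single
state variable — vessel volume `v` — determines the central mean arterial
pressure through a strictly monotone polynomial pressure–volume (P–V)
map on normalized volume `u = (v − v_min)/(v_max − v_min)`. The update is
an explicit fixed-step integration at `dt = 0.02 s` (50 Hz, matching the
pressure-transducer sampling rate of the benchtop rig the model emulates):

    v' = clamp(v + (Q_infusion − Q_internal − Q_bleed) · dt/60, v_min, v_max)

Volume bookkeeping is exactly conservative: if a step would run past a
vessel bound, the responsible flows are scaled back for that step (an
empty vessel cannot bleed) and a clamp event is logged, so
`v(t) − v(0) = infused − withdrawn` holds to 1e-6 mL on every run. This is
asserted by property tests with randomized command schedules.

Pulsatility is a zero-mean sinusoid at the configured heart rate (default
60 min⁻¹, peak-to-peak 20 mmHg) superimposed on the mean pressure; the
circulatory pump and bypass loop of a physical rig are not modeled
hydraulically — their only observable effect, a continuous pulsatile
central pressure independent of arm occlusion, is produced directly by
the waveform generator.

Derived channels:

* **occlusion fraction** `occ = clip(p_cuff / p_occ, 0, 1)` with
  `p_occ = 180 mmHg` by default — a piecewise-linear saturating stand-in
  for cuff–artery mechanics;
* **distal MAP** `max(0, central · (1 − occ) − Δp_arm)` with a 2 mmHg
  static arm drop;
* **extremity bleed** `(1 − occ) · max(distal, 0) / r_bleed`,
  `r_bleed = 0.25 mmHg·min/mL`, so an unoccluded bleed at ~75 mmHg runs
  at ~300 mL/min, commensurate with the internal-hemorrhage rates
  studied (120–360 mL/min);
* **cuff oscillation** `(1 − occ) · k_transmit · pulse_pressure`
  (`k_transmit = 0.2`), the oscillometric signature of a reopened artery.

### Default P–V curves

The porcine-derived curve coefficients used by the original benchtop
PhysioVessels are not published, so the package ships two synthetic
monotone cubics anchored at `p(1) = 95 mmHg`:

| infusate | coefficients (ascending, in u) | v_max | capacity 75→95 mmHg |
|---|---|---|---|
| whole blood | 30 + 80u − 20u² + 5u³ | 500 mL | ≈ 174 mL |
| crystalloid | 30 + 120u − 60u² + 5u³ | 1500 mL | ≈ 765 mL |

The crystalloid parameterization preserves the qualitative constraint that
restoring a given pressure span takes more than twice the whole-blood
volume (crystalloid redistributes out of the circulation). All
coefficients, ranges and resistances are user-configurable; a generator of
random strictly monotone cubic curves (`random_monotone_curve`) supports
robustness testing. Because the curves are synthetic, absolute volumes and
durations are not comparable to the physical rig; pressure thresholds,
event orderings, ratios and latencies are.

## ARC

Cycle structure: measure the 1-s windowed MAP at 1 Hz; pick the
intermediate setpoint `m + α·(target − m)` (α = 0.5 by default; only
"between the measured MAP and the target" is prescribed, so α is an open
parameter); convert the gap to a fractional volume deficit
`(V(setpoint) − V(m)) / (V(setpoint) − v_min)`; command
`cf · ((Q_max − Q_min)·err + Q_min)` clamped to `[Q_min, Q_max]`
(`Q_min = 50 mL/min`, an open parameter — only "near minimum value" is
stated; `Q_max = 1200 mL/min` as printed). On reaching the setpoint the
correction factor updates multiplicatively,
`cf ← clamp(cf · (t_actual/t_predicted) · scaling_factor, 0.1, 10)`;
the clamp keeps the recursion bounded. The composition of the correction
factor with the rate law is not written out in the source material; it is
implemented as a multiplicative gain on the rate, then clamped.

`t_predicted = 60·ΔV/rate` from the P–V curve; `t_actual` is measured
continuously (elapsed time since cycle start) so the suspected-hemorrhage
flag — raised when `(t_actual − t_predicted)/t_predicted ≥ 1`, i.e. the
actual time is twice the predicted — can fire mid-cycle. While raised it
forces `Q_max`; it clears at the next cycle boundary when the criterion is
re-evaluated afresh. Termination: first 1-Hz sample with windowed MAP
≥ 0.995 · target (the windowed rather than raw MAP is used; at a 60 min⁻¹
heart rate the 1-s window spans exactly one cardiac cycle, making the
windowed mean an unbiased MAP estimate).

An opt-in `deviation_scaled` adaptation variant
`cf ← cf·(1 + sf·(t_actual/t_predicted − 1))` is provided for
experimentation; the default follows the multiplicative update as printed.
Under the multiplicative update a 2× scaling factor compounds the
correction factor cycle over cycle and roughly doubles the peak rate; it
does not pin the pump at `Q_max` from the first cycle, and no claim about
relative total resuscitation times across scaling factors is asserted.

### Known limitation: hemorrhage-flag duty at severe hemorrhage

In this simulator the controller's P–V model equals the plant's by
construction, so time predictions are exact in the absence of hemorrhage.
Consequently, during a 360 mL/min hemorrhage the flag is active for
roughly a fifth of the infusion, not the majority: the moment the flag
forces 1200 mL/min the net fill rate (840 mL/min) out-runs the prediction
the error is measured against, and the criterion self-clears at the next
cycle. Sustained flag activity requires a chronically optimistic
prediction — i.e. real plant–model mismatch from pump spin-up, tubing
compliance and transport delays, which physical rigs have and this
idealized plant deliberately does not. The corresponding behavioral test
documents this as an expected divergence between the idealized simulation
and bench data.

## aTKT

Tightening: +25 mmHg per step, 2 s dwell, occlusion verified when distal
peak-to-peak pulsatility stays below 0.5 mmHg for a full dwell (the first
decision is likewise taken only after one observation dwell, so an
already-occluded start terminates with zero steps). The internal control
law of the physical self-tightening tourniquet is not reproduced; only
its externally specified behavior is.

Loosening classification on a 4-s cuff window (≥ 2 cardiac cycles):
mechanical failure iff the windowed mean has dropped strictly more than
33 % below the stored engagement pressure; otherwise re-bleed iff cuff
peak-to-peak ≥ 2 mmHg; otherwise ok. Mechanical failure takes precedence —
a collapsed bladder implicates hardware regardless of oscillation. The
window length and oscillation threshold are open parameters with the
stated defaults.

## SACM

Concurrency is cooperative scheduling on the single simulation clock: each
50 Hz step every active sub-controller contributes its actuator command,
and monitoring ticks (every 15 s) interleave without blocking. This
preserves the observable contract of the original multi-process design —
monitoring never blocks while a sub-controller runs; no sub-controller is
ever started twice — without OS-level processes. Monitoring begins the
instant the initial resuscitation completes. The MAP check uses the
windowed MAP at the tick instant with no hysteresis; a completed
resuscitation immediately re-arms the low-MAP trigger. A tourniquet
re-engagement does not suppress the low-MAP check in the same tick (both
conditions are evaluated independently, which is what allows simultaneous
complications to be handled in one tick). Worst-case loosening-to-
re-engagement latency is one full monitoring period plus one tick of
detection, ≤ 30 s with the 15-s default.

## Scenarios

Scenario files are YAML: ordered intervals, each with events injected at
the interval start (`set_internal_hemorrhage`, `open_extremity_valve`,
`loosen_tourniquet`, `start_sacm`) and an end condition (windowed MAP
threshold, next supervisor event of a kind, or fixed duration). The
"manual" operator actions of the emulated protocol become scheduled
events: the initial hemorrhage (240 mL/min) stops when MAP falls below
75 mmHg; loosening multiplies the held cuff pressure by 0.55, which both
exceeds the 33 % failure-drop rule and re-admits pulse transmission.

The five bundled scenarios: #1 initial stabilization only (3 intervals);
#2 two loosenings; #3 two resuscitations against a persistent internal
hemorrhage; #4 loosening then hemorrhage; #5 hemorrhage then loosening
while the hemorrhage continues (simultaneous complications; 5 intervals
each). In scenario #2 the re-bleed volume lost during the ≤15 s detection
latency (~15 mL per loosening) lowers the final MAP to ~93 mmHg without
crossing the 85 mmHg intervention threshold, so — as on the bench — no
additional resuscitation runs and that fluid is not recovered.

Telemetry is a tidy CSV, one row per 0.02 s tick, with the five reported
channels plus vessel volume; timestamp alignment across channels is
trivial by construction. Interval binning maps time within interval n to
normalized coordinates [n−1, n] (three bins for scenario #1, five for the
rest) so replicates align; heatmaps resample replicate rate traces to a
common 1 Hz grid spanning the longest trace and normalize by the
1200 mL/min pump maximum.

## Numerical choices

* P–V inversion by bracketed root finding (Brent), round-trip accurate to
  1e-6 of the volume span; an independent bisection oracle checks it in
  the test suite.
* Sensor noise is off by default; when enabled it is additive Gaussian
  with a mandatory seed, and every stochastic path (noise, scenario
  loosening offsets) derives from explicit seeds, so identical seeds give
  bit-identical telemetry.
* Degenerate guards: `t_predicted ≤ 0` skips the correction-factor update
  with a warning; a measured MAP above the setpoint yields zero volume
  error; an empty detection window and non-positive resistances raise.

## What the simulation does and does not show

Passing tests demonstrate the *logic* of the controllers and supervisor —
thresholds, event ordering, re-entrancy, latency bounds, conservation —
under an idealized plant whose P–V model the controllers know exactly.
They do not demonstrate performance under model mismatch, measurement
artifacts, pump dynamics, or biological compliance changes; absolute
volumes and durations depend on the synthetic default curves and should
not be compared to bench or animal data. Problem sizes were chosen for
desk-scale runs: scenarios simulate 2–6 minutes of loop time and complete
in well under a second each.
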