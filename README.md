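# sacm — supervisory closed-loop hemorrhage management, simulated

`sacm` is a desktop simulation of an autonomous trauma-care stack: a
supervisory controller (SACM) that coordinates two closed-loop medical
sub-systems — an **adaptive resuscitation controller (ARC)** that drives an
infusion pump to restore mean arterial pressure (MAP), and an **automated
pneumatic tourniquet (aTKT)** that occludes an extremity bleed — against a
simulated benchtop circulatory flow loop ("the patient"). It is aimed at
researchers in physiological closed-loop control who want to reproduce and
extend the controller logic end-to-end without hardware: every pump,
pressure transducer and cuff of the physical rig is replaced by a
discrete-time plant model with configurable pressure–volume (P–V) curves.

## The control stack

**Plant.** A vessel with a strictly monotone normalized P–V relationship
p(u), u ∈ [0, 1], supplies hydrostatic pressure to a pulsatile loop. Two
default curves are bundled: whole blood (PV_WB) and crystalloid (PV_C),
the latter parameterized so the fluid needed to traverse 75→95 mmHg is
more than twice the whole-blood volume. A tourniquet cuff occludes the arm
branch as a saturating function of cuff pressure; an extremity bleed
follows a linear orifice law on the distal pressure.

**ARC.** Each cycle picks an intermediate setpoint between the measured
MAP and the target, converts the pressure gap into a fractional volume
deficit through the P–V curve, and commands

    rate = (Q_max − Q_min) · volume_error + Q_min,

scaled by an adaptive correction factor updated from the ratio of the
actual to the P–V-predicted cycle time,

    cf_{n+1} = cf_n · (t_actual / t_predicted) · scaling_factor.

The run terminates once the 1-s windowed MAP reaches 99.5 % of the target.
Whenever the elapsed cycle time reaches twice the predicted time (100 %
prediction error), a *suspected hemorrhage* flag forces the pump to its
1200 mL/min maximum until the criterion clears.

**aTKT.** Tightens in 25 mmHg increments, dwelling 2 s each, until distal
pulsatility vanishes (occlusion verified; the cuff pressure at that moment
is the *engagement pressure*). Two loosening rules protect the occlusion:
cuff-pressure oscillations (re-bleed) and a >33 % drop from the engagement
pressure (mechanical failure).

**SACM.** Phase one is sequential: engage the tourniquet, then resuscitate
to target. Phase two checks two conditions every 15 s — tourniquet loose?
MAP below 85 mmHg? — and dispatches the corresponding sub-controller;
both can run concurrently, and a running instance is never started twice.

## Worked example

```python
from sacm import ArcConfig, FlowLoopPlant, PlantConfig, run_resuscitation

plant = FlowLoopPlant(PlantConfig(), initial_map=75.0)   # hemorrhaged patient
res = run_resuscitation(plant, ArcConfig(curve=plant.config.curve))
print(f"reached={res.reached_target} final_map={res.final_map:.2f} mmHg "
      f"infused={res.total_infused:.1f} mL in {res.duration:.0f} s")
```

prints

```
reached=True final_map=94.58 mmHg infused=171.1 mL in 59 s
```

— the controller stopped at the first 1-Hz sample with windowed MAP at or
above 0.995 · 95 = 94.525 mmHg, having infused the ~174 mL P–V volume gap
between 75 and 95 mmHg (minus the small remainder above 94.58 mmHg), with
rates tapering from 288 mL/min toward the 50 mL/min floor.

Full trauma scenarios run from the CLI:

```bash
sacm run-scenario --scenario scenario_3 --seed 1 --out out/
sacm run-arc-test --condition wb_hem_240 --replicates 3 --out out/
sacm report --in out/
```

`run-scenario` writes per-tick telemetry CSV (distal MAP, cuff pressure,
central MAP, infusion rate, fluid balance) and a JSON event stream
(`atkt_engaged`, `arc_started`, `loose_detected`, ...). Five scenarios are
bundled, from plain stabilization (`scenario_1`) to simultaneous
tourniquet loosening plus internal hemorrhage (`scenario_5`).

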