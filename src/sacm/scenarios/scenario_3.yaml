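# Scenario 3: initial stabilization, then an ongoing internal hemorrhage
# (240 mL/min) forces two monitoring-phase resuscitations before the bleed
# is stopped.
name: scenario_3
infusate: whole_blood
intervals:
  - events:
      - {action: set_internal_hemorrhage, rate_ml_min: 240}
    until: {map_below: 75.0}
    on_end:
      - {action: set_internal_hemorrhage, rate_ml_min: 0}
  - events:
      - {action: open_extremity_valve}
      - {action: start_sacm}
    until: {event: atkt_engaged}
  - until: {event: arc_completed}
    settle_s: 5
  - events:
      - {action: set_internal_hemorrhage, rate_ml_min: 240}
    until: {event: arc_completed}
  - until: {event: arc_completed}
    on_end:
      - {action: set_internal_hemorrhage, rate_ml_min: 0}
    settle_s: 5
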