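# Scenario 1: initial stabilization only.
# (0-1) initial hemorrhage to ~75 mmHg, (1-2) extremity bleed + tourniquet
# engagement, (2-3) resuscitation back to 95 mmHg.
name: scenario_1
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
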