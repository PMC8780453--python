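# Scenario 2: initial stabilization, then the tourniquet is loosened twice;
# the monitoring phase must detect each loosening and re-engage the cuff.
name: scenario_2
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
      - {action: loosen_tourniquet, fraction: 0.55}
    until: {event: atkt_engaged}
    settle_s: 5
  - events:
      - {action: loosen_tourniquet, fraction: 0.55}
    until: {event: atkt_engaged}
    settle_s: 5
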