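# Scenario 5: initial stabilization, then an internal hemorrhage with a
# resuscitation, followed by a tourniquet loosening while the hemorrhage is
# still running -- both complications occur simultaneously, so the
# monitoring phase must re-engage the cuff and start a third resuscitation.
name: scenario_5
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
  - events:
      - {action: loosen_tourniquet, fraction: 0.55}
    until: {event: arc_completed}
    on_end:
      - {action: set_internal_hemorrhage, rate_ml_min: 0}
    settle_s: 5
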