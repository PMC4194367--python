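"""One-way sensitivity: re-run a scenario pair at a parameter's bounds.

Every published input carries a (low, high) range — by convention ±25% of
the point value.  The sweep holds everything else at point values.
"""

import renalbudget as rb

inputs = rb.default_inputs()
for param in (
    "mortality.hr_high_dose_hd",
    "hospitalisation.year1.pd",
    "costs.transport_per_ichd_session",
):
    sweep = rb.one_way_sensitivity(param, scenario_id="s4", inputs=inputs)
    lo = sweep["bounds"]["low"]
    pt = sweep["bounds"]["point"]
    hi = sweep["bounds"]["high"]
    print(f"{param}:")
    print(f"  low  {lo['value']:>10}: s4−reference = £{lo['total_difference']:,.0f}")
    print(f"  point{pt['value']:>10}: s4−reference = £{pt['total_difference']:,.0f}")
    print(f"  high {hi['value']:>10}: s4−reference = £{hi['total_difference']:,.0f}")

print("\nThe interval around the point difference shows how much each input"
      "\ndrives the budget impact of shifting patients to home-based care.")
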