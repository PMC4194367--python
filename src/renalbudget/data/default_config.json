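{
  "_comment": "England NHS payer parameterisation of the dialysis modality budget-impact model. Probabilities printed as percentages carry units 'percent-per-28-days'; sensitivity ranges are derived as point x (1 +/- 0.25) rounded half-up at the printed precision unless an explicit low/high override is given. Survival curves are a synthetic parametric stand-in (assumption, not registry data).",
  "population": {
    "prevalent": 22993,
    "incident_per_year": 5395,
    "incident_entry_years": [2, 3, 4, 5]
  },
  "model": {
    "cycles_per_year": 13,
    "horizon_years": 5,
    "cycle_days": 28
  },
  "mortality": {
    "hr_high_dose_hd": {"point": 0.76, "units": "dimensionless", "decimals": 2},
    "hr_home_hd": {"point": 1.0, "low": 1.0, "high": 1.0, "units": "dimensionless", "decimals": 2}
  },
  "survival": {
    "dialysis": {"family": "exponential", "anchors": {"1.0": 0.88}},
    "transplant": {"family": "exponential", "anchors": {"1.0": 0.97}},
    "source": "synthetic parametric stand-in (assumption, not registry data)"
  },
  "transitions": {
    "transplant_rate": {"point": 0.007, "units": "probability-per-28-days", "decimals": 3},
    "graft_failure": {"point": 0.004, "units": "probability-per-28-days", "decimals": 3},
    "ichd_to_home_hd": {
      "months_0_12": {"point": 0.05, "units": "percent-per-28-days", "decimals": 2},
      "months_13_18": {"point": 0.03, "units": "percent-per-28-days", "decimals": 2},
      "months_19_plus": {"point": 0.0, "units": "percent-per-28-days", "decimals": 2}
    },
    "home_hd_to_ichd": {"point": 0.38, "units": "percent-per-28-days", "decimals": 2},
    "hd_to_pd": {
      "months_0_6_incident": {"point": 1.95, "units": "percent-per-28-days", "decimals": 2},
      "months_0_6_prevalent": {"point": 1.08, "units": "percent-per-28-days", "decimals": 2},
      "months_7_12": {"point": 0.2, "units": "percent-per-28-days", "decimals": 2},
      "months_13_18": {"point": 0.07, "low": 0.05, "high": 0.08, "units": "percent-per-28-days", "decimals": 2},
      "months_19_plus": {"point": 0.06, "low": 0.04, "high": 0.07, "units": "percent-per-28-days", "decimals": 2}
    },
    "pd_to_hd": {
      "months_0_6_incident": {"point": 2.61, "units": "percent-per-28-days", "decimals": 2},
      "months_0_6_prevalent": {"point": 1.87, "units": "percent-per-28-days", "decimals": 2},
      "months_7_12": {"point": 1.13, "units": "percent-per-28-days", "decimals": 2},
      "months_13_18": {"point": 0.78, "low": 0.59, "high": 0.97, "units": "percent-per-28-days", "decimals": 2},
      "months_19_plus": {"point": 0.31, "units": "percent-per-28-days", "decimals": 2}
    }
  },
  "hospitalisation": {
    "followup_ratio": 0.69,
    "year1_percent": {
      "ichd_conventional": {"point": 7.05, "units": "percent-per-28-days", "decimals": 2},
      "home_hd_conventional": {"point": 5.35, "low": 4.01, "high": 6.68, "units": "percent-per-28-days", "decimals": 2},
      "hd_high_dose": {"point": 7.09, "units": "percent-per-28-days", "decimals": 2},
      "pd": {"point": 6.69, "units": "percent-per-28-days", "decimals": 2}
    },
    "event_cost": {
      "hd": {"point": 1904, "low": 1482, "high": 2380, "units": "GBP", "decimals": 0},
      "pd": {"point": 1596, "units": "GBP", "decimals": 0}
    }
  },
  "costs": {
    "vascular_access": {"point": 1287, "units": "GBP", "decimals": 0},
    "peritoneal_access": {"point": 1233, "low": 854, "high": 1423, "units": "GBP", "decimals": 0},
    "ichd_session_catheter": {"point": 121, "low": 92, "high": 154, "units": "GBP-per-session", "decimals": 0},
    "ichd_session_fistula": {"point": 152, "low": 115, "high": 191, "units": "GBP-per-session", "decimals": 0},
    "ichd_session_weighted": {"point": 147, "units": "GBP-per-session", "decimals": 0},
    "home_hd_weekly": {"point": 456, "units": "GBP-per-week", "decimals": 0},
    "apd_daily": {"point": 52, "units": "GBP-per-day", "decimals": 0},
    "capd_daily": {"point": 46, "units": "GBP-per-day", "decimals": 0},
    "esa_per_1000_units": {"point": 5.09, "units": "GBP", "decimals": 2},
    "esa_dose_hd_units_per_week": {"point": 6705, "units": "units-per-week", "decimals": 0},
    "esa_dose_pd_units_per_week": {"point": 3700, "units": "units-per-week", "decimals": 0},
    "monitoring_single": {"point": 132, "units": "GBP", "decimals": 0},
    "monitoring_multi": {"point": 247, "units": "GBP", "decimals": 0},
    "monitoring_visits_per_year": 2,
    "hospitalisation_event_hd": {"point": 1904, "low": 1482, "high": 2380, "units": "GBP", "decimals": 0},
    "hospitalisation_event_pd": {"point": 1596, "units": "GBP", "decimals": 0},
    "transport_per_ichd_session": {"point": 46, "units": "GBP-per-session", "decimals": 0},
    "transplant_procedure": {"point": 18579, "units": "GBP", "decimals": 0},
    "post_transplant_medication_annual": {"point": 11137, "low": 8352, "high": 13921, "units": "GBP", "decimals": 0},
    "sessions_per_week_conventional": 3,
    "sessions_per_week_high_dose": 5
  },
  "flags": {
    "charge_prevalent_baseline_access": true,
    "monitor_post_transplant": false,
    "prevalent_hospitalisation_year1": false,
    "apd_share": 0.5,
    "per_patient_denominator": "years_lived"
  },
  "scenarios": {
    "reference": {
      "prevalent_percent": {"pd": 14.1, "ichd_conventional": 82.0, "ichd_high_dose": 0.0, "home_hd_conventional": 3.9, "home_hd_high_dose": 0.0},
      "incident_percent": {"pd": 22.9, "ichd_conventional": 77.1, "ichd_high_dose": 0.0, "home_hd_conventional": 0.0, "home_hd_high_dose": 0.0},
      "home_hd_high_dose_weekly_tariff": 456
    },
    "s1": {
      "prevalent_percent": {"pd": 14.1, "ichd_conventional": 72.0, "ichd_high_dose": 0.0, "home_hd_conventional": 3.9, "home_hd_high_dose": 10.0},
      "incident_percent": {"pd": 22.9, "ichd_conventional": 77.1, "ichd_high_dose": 0.0, "home_hd_conventional": 0.0, "home_hd_high_dose": 0.0},
      "home_hd_high_dose_weekly_tariff": 456
    },
    "s2": {
      "prevalent_percent": {"pd": 14.1, "ichd_conventional": 72.0, "ichd_high_dose": 0.0, "home_hd_conventional": 3.9, "home_hd_high_dose": 10.0},
      "incident_percent": {"pd": 22.9, "ichd_conventional": 77.1, "ichd_high_dose": 0.0, "home_hd_conventional": 0.0, "home_hd_high_dose": 0.0},
      "home_hd_high_dose_weekly_tariff": 575
    },
    "s3": {
      "prevalent_percent": {"pd": 20.0, "ichd_conventional": 66.1, "ichd_high_dose": 0.0, "home_hd_conventional": 3.9, "home_hd_high_dose": 10.0},
      "incident_percent": {"pd": 31.0, "ichd_conventional": 69.0, "ichd_high_dose": 0.0, "home_hd_conventional": 0.0, "home_hd_high_dose": 0.0},
      "home_hd_high_dose_weekly_tariff": 575
    },
    "s4": {
      "prevalent_percent": {"pd": 25.0, "ichd_conventional": 61.1, "ichd_high_dose": 0.0, "home_hd_conventional": 3.9, "home_hd_high_dose": 10.0},
      "incident_percent": {"pd": 39.0, "ichd_conventional": 61.0, "ichd_high_dose": 0.0, "home_hd_conventional": 0.0, "home_hd_high_dose": 0.0},
      "home_hd_high_dose_weekly_tariff": 575
    },
    "s5": {
      "prevalent_percent": {"pd": 0.0, "ichd_conventional": 100.0, "ichd_high_dose": 0.0, "home_hd_conventional": 0.0, "home_hd_high_dose": 0.0},
      "incident_percent": {"pd": 0.0, "ichd_conventional": 100.0, "ichd_high_dose": 0.0, "home_hd_conventional": 0.0, "home_hd_high_dose": 0.0},
      "home_hd_high_dose_weekly_tariff": 456
    }
  }
}
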