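{
  "notes": "Stakeholder attribution of the reference study's combined (all-methods, as-conducted) costs. The printed employer-administration column total is 2393 but the printed cells sum to 2392; this fixture carries the cells.",
  "shares": {
    "meetings": {"researcher": 1170, "employer_admin": 1170},
    "administration": {"researcher": 1897, "employer_admin": 754},
    "recruitment_admin": {"researcher": 1748, "employer_admin": 468},
    "equipment": {"researcher": 10526},
    "training": {"researcher": 7686, "worker_production": 260},
    "recruitment_time": {"researcher": 1413},
    "measurement_travel": {"researcher": 7659},
    "measurement_preparation": {"researcher": 6456, "worker_production": 4162},
    "measurement_time_supplies": {"researcher": 25539}
  }
}
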