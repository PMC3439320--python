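{
  "baseline_design": {"n_t": 30, "n_n": 38, "n_w": 27, "n_d": 51, "n_m": 80, "n_c": 29},
  "scenarios": [
    {
      "name": "sim1_no_accommodation",
      "notes": "Travel to and from the worksite on every researcher-day; no overnight stays.",
      "design_overrides": {"n_t": 51, "n_n": 0}
    },
    {
      "name": "sim2_one_worker_per_researcher_day",
      "notes": "One worker measured per researcher-day: 80 researcher-days, no concurrency; every worker-day requires its own recruit in this scenario's published parameters.",
      "design_overrides": {"n_t": 45, "n_n": 60, "n_w": 80, "n_d": 80, "n_c": 0}
    },
    {
      "name": "sim3_four_workers_per_researcher_day",
      "notes": "Four workers measured concurrently per researcher-day: 20 researcher-days.",
      "design_overrides": {"n_t": 14, "n_n": 15, "n_d": 20, "n_c": 60}
    },
    {
      "name": "sim4_no_travel_costs",
      "notes": "Worksite adjacent to the institution: travel unit cost 0 and no accommodation nights.",
      "design_overrides": {"n_n": 0},
      "unit_cost_overrides": {"shared": {"trip": {"mean": 0, "sd": null}}}
    },
    {
      "name": "sim5_no_equipment_costs",
      "notes": "All equipment previously purchased: every equipment component set to 0. The published scenario tables label zero-equipment as scenario 5 and tenfold recruitment as scenario 6; the accompanying prose swaps the two labels, and these fixtures follow the tables, whose totals are internally consistent.",
      "fixed_cost_overrides": {
        "shared": {"equipment": 0},
        "inclinometer": {"equipment": 0},
        "video_observation": {"equipment": 0},
        "daily_questionnaire": {"equipment": 0}
      }
    },
    {
      "name": "sim6_recruitment_costs_tenfold",
      "notes": "Recruitment unit cost increased tenfold (22 to 220 per worker).",
      "unit_cost_overrides": {"shared": {"recruit": {"mean": 220}}}
    }
  ]
}
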