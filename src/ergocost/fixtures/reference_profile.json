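{
  "currency_label": "EUR",
  "notes": "Reference cost profile for a 27-worker, 80-worker-day posture study at a Swedish airport; unit costs printed rounded to whole euros. Blank method-specific supply cells are read as 0 (logged on load). Video-observation method-specific equipment 2095 and training 693; the questionnaire has no method-specific equipment.",
  "shared_fixed": {
    "meetings": 2340,
    "administration": 2548,
    "recruitment_admin": 2216,
    "equipment": 2401,
    "training": 4916
  },
  "per_method_fixed": {
    "inclinometer": {"equipment": 6030, "training": 1777},
    "video_observation": {"equipment": 2095, "training": 693},
    "daily_questionnaire": {"training": 559}
  },
  "shared_unit": {
    "trip": {"mean": 273, "sd": 159},
    "night": {"mean": 149, "sd": 22},
    "recruit": {"mean": 22, "sd": 14}
  },
  "per_method_unit": {
    "inclinometer": {
      "supplies": {"mean": 1},
      "first_worker": {"mean": 508},
      "concurrent_worker": {"mean": 83, "sd": 49}
    },
    "video_observation": {
      "supplies": {"mean": 0},
      "first_worker": {"mean": 342},
      "concurrent_worker": {"mean": 216, "sd": 70}
    },
    "daily_questionnaire": {
      "supplies": {"mean": 4},
      "first_worker": {"mean": 135},
      "concurrent_worker": {"mean": 9, "sd": 8}
    }
  }
}
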