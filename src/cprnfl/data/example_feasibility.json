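{
  "description": "Example feasibility tallies from a pediatric hand-held OCT study: eyes attempted / imageable per group, factors preventing 3D acquisition, and per-quadrant success rates among imageable eyes (printed to 0.1%).",
  "groups": [
    {
      "group": "glaucoma",
      "eyes_attempted": 256,
      "eyes_possible": 188,
      "factor_counts": {
        "nystagmus": 24,
        "cloudy_or_opaque_media": 30,
        "high_refractive_error": 10,
        "small_pupils": 2,
        "other": 2
      },
      "success_rate_possible_pct": {
        "nasal": 85.1,
        "temporal": 88.8,
        "inferior": 82.4,
        "superior": 77.1,
        "full": 67.0
      }
    },
    {
      "group": "controls",
      "eyes_attempted": 360,
      "eyes_possible": 360,
      "factor_counts": {},
      "success_rate_possible_pct": {
        "nasal": 97.2,
        "temporal": 98.6,
        "inferior": 92.8,
        "superior": 93.6,
        "full": 88.9
      }
    }
  ]
}
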