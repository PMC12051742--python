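{
  "config": {
    "generation_time": 5.79,
    "mutation_rate": 3.18e-09,
    "rng_seed": null
  },
  "migration_epochs": [
    {
      "end_time": 31200.0,
      "rates": {
        "EURw->SPA": 9.52e-05,
        "SPA->EURw": 9.7e-05
      },
      "start_time": 0.0
    },
    {
      "end_time": 107000.0,
      "rates": {
        "EURns->IRQ": 4.41e-05,
        "IRQ->EURns": 8.82e-06
      },
      "start_time": 0.0
    },
    {
      "end_time": 30600.0,
      "rates": {
        "EURns->EURw": 0.000242,
        "EURw->EURns": 9.32e-05
      },
      "start_time": 0.0
    }
  ],
  "name": "gws",
  "populations": [
    {
      "growth_rate": 0.0,
      "growth_start_time": 0.0,
      "n_diploid_samples": 15,
      "name": "SPA",
      "ne_present": 50000.0
    },
    {
      "growth_rate": 3.74e-05,
      "growth_start_time": 28000.0,
      "n_diploid_samples": 15,
      "name": "EURw",
      "ne_present": 200000.0
    },
    {
      "growth_rate": 8.74e-05,
      "growth_start_time": 17800.0,
      "n_diploid_samples": 15,
      "name": "EURns",
      "ne_present": 400000.0
    },
    {
      "growth_rate": 0.0,
      "growth_start_time": 0.0,
      "n_diploid_samples": 5,
      "name": "IRQ",
      "ne_present": 20000.0
    }
  ],
  "splits": [
    {
      "ancestral_ne": 100000.0,
      "ancestral_pop": "SPA",
      "derived_pop": "EURw",
      "time": 31200.0
    },
    {
      "ancestral_ne": 100000.0,
      "ancestral_pop": "IRQ",
      "derived_pop": "EURns",
      "time": 107000.0
    },
    {
      "ancestral_ne": 100000.0,
      "ancestral_pop": "SPA",
      "derived_pop": "IRQ",
      "time": 428000.0
    }
  ]
}
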