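{
  "config": {
    "generation_time": 5.79,
    "mutation_rate": 3.18e-09,
    "rng_seed": null
  },
  "migration_epochs": [
    {
      "end_time": 34500.0,
      "rates": {
        "EURw->SPA": 0.000169,
        "SPA->EURw": 0.000316
      },
      "start_time": 0.0
    },
    {
      "end_time": 131000.0,
      "rates": {
        "EURns->IRQ": 4.52e-05,
        "IRQ->EURns": 5.68e-06
      },
      "start_time": 0.0
    },
    {
      "end_time": 20000.0,
      "rates": {
        "EURns->EURw": 0.000694,
        "EURw->EURns": 0.000129
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
      "growth_rate": 0.000235,
      "growth_start_time": 3100.0,
      "n_diploid_samples": 15,
      "name": "EURw",
      "ne_present": 200000.0
    },
    {
      "growth_rate": 0.000254,
      "growth_start_time": 34500.0,
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
      "time": 34500.0
    },
    {
      "ancestral_ne": 100000.0,
      "ancestral_pop": "IRQ",
      "derived_pop": "EURns",
      "time": 131000.0
    },
    {
      "ancestral_ne": 100000.0,
      "ancestral_pop": "SPA",
      "derived_pop": "IRQ",
      "time": 504000.0
    }
  ]
}
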