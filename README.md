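# crowdemog

Demographic model comparison for the European crow hybrid zone: coalescent
simulation, folded joint-SFS composite likelihood, topology weighting, and
introgression statistics.

## The problem

All-black carrion crows of Western Europe (EURw) look like their Iberian
congeners (SPA) but are genomically near-identical to grey-coated hooded
crows (EURns) — except for a single plumage locus on chromosome 18.  Two
histories explain this mosaic:

- **Genome-wide swamping (GWS)** — population tree
  `((SPA,EURw),(EURns,IRQ))`: EURw descends from the Iberian refugium and
  massive post-contact gene flow from hooded crows homogenised its genome;
  the colour locus is a barrier locus held by divergent selection and
  still reflects the species tree.
- **Locus-specific introgression (LSI)** — tree
  `((IRQ,(EURw,EURns)),SPA)`: EURw shares recent ancestry with hooded
  crows, and only the colour locus crossed the Pyrenees from Iberia.

`crowdemog` implements the inference chain that discriminates the two
scenarios, exercisable end to end on synthetic data: an exact structured-
coalescent engine for four-population isolation-with-migration histories
(splits, per-branch sizes, exponential growth, epochs of asymmetric
migration), folded joint site-frequency spectra of the six population
pairs, simulation-based composite-likelihood fitting with ECM-style
conditional maximisation, AIC model choice
(`AIC = 2k − 2 ln(10) log10 L`) and parametric bootstrap with bias
correction, Twisst-style topology weighting of 50-SNP block gene trees
with ternary binning (400 cells), and the windowed statistics pi, d_XY,
Hudson's F_ST, d_a = d_XY − (pi_x+pi_y)/2, Tajima's D, Patterson's D,
f4-ratios, f_dM, the four-gamete fraction and exact Hardy-Weinberg
filtering.  The synthetic-data generator writes phased VCFs with a
chr18-like barrier region (migration zeroed locally, emulating divergent
selection's effect on effective migration) and a truth record for
byte-identical regeneration.

See `docs/methods.md` for the model, estimators, defaults and the scales
used in the checks.

## Worked example

Fit both scenarios to synthetic spectra generated under genome-wide
swamping at the published point estimates, freeing the refugial divergence
time and the hooded-to-carrion migration rate:

```python
from crowdemog import build_gws_model, build_lsi_model, GWS_FASTSIMCOAL
from crowdemog.sfs_inference import (CompositeLikelihoodModel,
                                     FreeParameter, simulate_observed_set)

model = build_gws_model(GWS_FASTSIMCOAL)
obs = simulate_observed_set(model, n_loci=2000, locus_length=2000, seed=1)
free = [FreeParameter("t_anc", 150e3, 1e6),
        FreeParameter("m_eurns_eurw", 1e-5, 5e-3, "log")]
fits = {}
for builder in (build_gws_model, build_lsi_model):
    clm = CompositeLikelihoodModel(obs, builder, GWS_FASTSIMCOAL, free,
                                   n_sim_loci=400, locus_length=2000)
    fits[clm.name] = clm.fit(n_cycles=2, seed=1, n_evals_per_param=6,
                             final_n_sim_loci=2000)
print(fits["gws"].summary())
print(f"AIC (gws) = {fits['gws'].aic:,.0f}")
print(f"AIC (lsi) = {fits['lsi'].aic:,.0f}")
```

prints

```
Composite-likelihood fit: gws
  pairs:            EURns-IRQ, EURw-EURns, EURw-IRQ, SPA-EURns, SPA-EURw, SPA-IRQ
  sites:            194125
  free parameters:  2
  log10 L:          -334048.8450
  AIC:              1538355.78
  estimates:
   *m_eurns_eurw     0.000815495
   *t_anc            598684
    t_eurns          131000
    ...
  (* = optimised)
AIC (gws) = 1,538,356
AIC (lsi) = 1,543,938
```

The generating scenario wins by ~5,600 AIC units: the 194,125 synthetic
sites carry a clear signal for the swamping topology even at this small
scale.  The two freed parameters land near their generating values
(504 kya; 6.94e-4) within the uncertainty of a 2,000-locus dataset; the
profile machinery (`clm.profile`) and the parametric bootstrap
(`fits["gws"].parametric_bootstrap()`) quantify that uncertainty.

A thin CLI wraps the same library calls
(`crowdemog generate | stats | sfs | fit | bootstrap | twisst | compare |
run-all`); `crowdemog compare --seed 1 --report report.json` runs the full
desk-scale chain and reports the AIC table, winner, and ternary L1
distances.

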