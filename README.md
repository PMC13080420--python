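# peapheno

Image-based drought phenotyping for pea (*Pisum* spp.) germplasm panels.

High-throughput phenotyping platforms screen large diversity panels for
drought tolerance by imaging every plant instead of measuring it by hand:
side-view RGB frames at six turn-table angles, a top-view spectral
reflectance stack, and a dark-adapted chlorophyll-fluorescence pair. This
package implements the full analysis for such an experiment — a panel of
accessions grown under control (70% field capacity) and drought (30% field
capacity) irrigation in a completely randomized design — from raster to
report:

* **Trait extraction** (`peapheno.image_traits`): chroma-rule segmentation
  against the blue imaging background; per-view projected area; digital
  biomass DB (mean of the six side-view areas); convex hull area CH
  (monotone-chain hull of pixel centers, shoelace area); solidity
  SOL = DB / CH; pixel height; top area TA; the RGB vegetation indices
  NDVI = (G−R)/(G+R), NPCI = (R−B)/(R+B), PSRI = (R−B)/G,
  GLI = (2G−R−B)/(2G+R+B); and PSII photochemical efficiency
  PhE = Fv/Fm = (Fm − F0)/Fm.
* **Derived traits and sensitivity** (`peapheno.derived`): SLA, LWR, LAR,
  RWC = (FW−DW)/(SFW−DW)×100, WUE = DB / water used, and the drought
  sensitivity index

  SI = (x̄_control − x̄_drought) / x̄_control × 100

  per trait, per accession, and per species group.
* **Statistics** (`peapheno.stats`): balanced two-way ANOVA; all-random
  variance components by the expected-mean-squares method (equal to REML
  for balanced data at interior solutions); relative contributions of
  genotype, condition, interaction and residual; broad-sense heritability
  h² = σ²G/(σ²G + σ²GC + σ²E) (plot basis; entry-mean basis available);
  per-condition CV; Pearson correlation networks; correlation-matrix PCA.
* **Synthetic data with ground truth** (`peapheno.phantoms`,
  `peapheno.simulate`): stick-model plant phantoms whose true area, height,
  hull, index and Fv/Fm values are known by construction, and trait tables
  drawn from the additive model y = μ + G + C + GC + ε at chosen variance
  components — so every stage is testable end to end without the original
  raw images.

## Worked example

```python
from peapheno import (SimulationParams, simulate_trait_table, two_way_anova,
                      estimate_variance_components, heritability)

table = simulate_trait_table(SimulationParams(
    n_accessions=60, n_reps=3, sigma2_G=2.0, sigma2_GC=1.0, sigma2_E=1.0, seed=7,
), trait="DW")
vc = estimate_variance_components(two_way_anova(table, "DW"))
print(round(vc.sigma2_g, 3), round(vc.sigma2_gc, 3), round(vc.sigma2_e, 3))
print(round(heritability(vc), 3))
```

prints

```
1.449 0.934 0.857
0.447
```

— the decomposed genotype, genotype×condition and residual variances of one
simulated dry-weight experiment (true values 2, 1, 1), and the plot-basis
broad-sense heritability (true value 0.5; single-experiment estimates
scatter around it, and the test suite verifies they are unbiased over 200
replicate simulations).

The `examples/` directory holds one short script per capability: phantom
rendering and exact trait recovery, spectral/fluorescence index extraction,
sensitivity indices, variance components and heritability, correlation
networks and PCA, and the full simulate → extract → stats pipeline. The
pipeline is also exposed as a thin CLI:

```bash
peapheno simulate --n-accessions 10 --n-reps 2 --seed 5 --out run/
peapheno extract  --manifest run/manifest.json --out run/traits.csv
peapheno stats    --table run/traits.csv --out run/report/
```

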