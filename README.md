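# actigut

Links device-measured movement behaviour to the gut microbiome. The
package takes minute-level hip-accelerometer counts and a faecal
shotgun-metagenomics abundance table and asks, feature by feature, how
the composition of awake time — sedentary behaviour (SED) and light
(LIPA), moderate (MPA) and vigorous (VPA) physical activity — relates to
species and functional-module abundances, and how much of the
between-person community dissimilarity the time-use composition explains.

It is written for epidemiologists and microbiome analysts who need the
full chain as tested, reusable code: accelerometer processing with
explicit non-wear and valid-day rules, compositional transforms with
principled zero handling, a calibrated per-feature association engine,
and permutation-based ordination — plus a synthetic-data generator with
known planted structure, so every stage can be validated end to end.

## The model

Time spent in the four intensity classes is a composition (the parts sum
to total wear time), so the exposures enter models as additive log-ratios
with LIPA as the reference:

    alr_X = ln(X / LIPA),  X ∈ {SED, MPA, VPA'},  VPA' = VPA + 0.1

standardized to z-scores. Microbiome features are centered log-ratio
transformed with a pseudocount and detection-limit zero replacement:

    y_f = ln(x_f + pc) − mean_g ln(x_g + pc)

For each feature f the joint model

    y_f = β_SED·z_SED + β_MPA·z_MPA + β_VPA·z_VPA + γ'C + ε

is compared with the covariates-only model by a 3-df likelihood-ratio
test; Benjamini–Hochberg controls the FDR at 5%; a dfbeta influence
screen discards associations driven by a single observation; a Wald
contrast tests β_MPA = β_VPA. Community-level structure is assessed by
partial distance-based redundancy analysis of the Bray–Curtis matrix on
the three exposures, conditioning on covariates, with Freedman–Lane
permutation p-values.

## Worked example

```python
from actigut import (SynthConfig, generate_covariates, generate_timeuse,
                     generate_microbiome, prevalence_filter, clr_transform,
                     ClrPolicy, FeatureAssociationModel)
import pandas as pd

cfg = SynthConfig(n_participants=500, n_species=200, seed=2,
                  effect_table=(("sp_0001", "MPA", 0.5),))
cov = generate_covariates(cfg)
timeuse = generate_timeuse(cfg)
exposures = timeuse[["z_alr_SED", "z_alr_MPA", "z_alr_VPA"]]
species, _ = generate_microbiome(cfg, exposures, cov)
kept, _ = prevalence_filter(species)
clr = clr_transform(kept, ClrPolicy.species())
covariates = pd.concat([cov, timeuse[["wear_minutes", "pct_weekend_wear"]]], axis=1)

res = FeatureAssociationModel(clr, exposures, covariates).fit()
print(res.summary(3))
```

```
Feature association results — main model
  samples: 500   design columns: 39
  features tested: 188   significant (q<0.05): 1
  discarded by influence screen: 0
  max VIF among exposures: 1.422 (z_alr_MPA)

         beta_SED  beta_MPA  beta_VPA     lrt_p         q
sp_0001   0.07485    0.5555  -0.03805 1.099e-34 2.067e-32
```

The one feature carrying a planted effect of +0.5 clr units per SD of
alr-MPA is recovered (β̂_MPA = 0.56, within sampling error), nothing else
crosses q < 0.05, and the exposure VIFs stay near 1.4 — the same order
reported for jointly entered alr exposures in large cohorts.

The command line mirrors the library stage by stage:

```bash
actigut all --seed 1 --out myrun/      # generator → ... → ordination
actigut accel --counts counts.csv --out timeuse.tsv
actigut assoc --features clr.tsv --exposures timeuse.tsv \
              --covars covariates.csv --model main --out results/
```

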