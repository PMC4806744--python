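# bearsalmon

A tested, reusable pipeline for bear-salmon ecophysiology: from raw
salmon escapement records and bear hair samples to per-bear salmon
availability, stable-isotope diet fractions, and AICc-ranked hormone
models — plus a synthetic study generator with known ground truth so
every stage can be verified end to end.

## Who this is for

Wildlife ecophysiologists and quantitative ecologists working with
hair-snag style datasets: spawner counts per stream × species × year
(with the usual ~30% missingness), bear detection locations, and hair
assays of δ13C/δ15N, cortisol, and testosterone. The package turns these
four tables into analysis-ready bear-year rows and ranked regression
models, and ships a generator that emulates the whole study so methods
can be validated before touching field data.

## What it computes

1. **Escapement imputation** — missing spawner counts filled with a
   two-way additive model on log(count+1)
   (`α[stream, species] + γ[species, year]`, alternating-means fit),
   validated by leave-one-out cross-validation with a log-scale
   coefficient of variability (CV = 100·sd(obs, pred)/mean(obs, pred)).
   Counts convert to biomass via per-species mass (kg/fish) and to
   biomass per km of spawning reach.
2. **Salmon availability** — for each bear-year, a regular grid of 40
   candidate circular buffers (home-range radius r = √(area/π), lattice
   spacing r/4) around each detection; the buffer maximising the 10-year
   mean biomass B10 is the estimated home range, yielding the triplet
   (B10, Bt, Bt1). A correlation-matrix PCA of the log triplet gives
   "watershed productivity" (PC1) and "salmon availability" (PC2).
3. **Diet fraction** — a two-source (salmon/plants) Bayesian mixing
   model on δ13C/δ15N with source, discrimination, and residual
   uncertainty: mean_j(p) = p(μ_sj+λ_sj) + (1−p)(μ_pj+λ_pj),
   sd_j(p)² = p²(σ_sj²+τ_sj²) + (1−p)²(σ_pj²+τ_pj²) + ε_j². The
   posterior over p is computed by exact grid quadrature (an optional
   Metropolis sampler cross-checks it), with median and 95% credible
   interval per bear-year.
4. **Hormone models** — >2 SD outlier screening, arcsine-sqrt /
   ln / negative-reciprocal transforms, standardization, VIF and
   correlation screening, a priori candidate model sets in
   environment / individual / combined categories, OLS fits ranked by
   AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with Akaike weights, a
   ΔAICc ≤ 2 top set, and group-relative weights ω. Wilcoxon rank-sum
   tests with Holm-Bonferroni adjustment and a two-sided F variance-ratio
   test cover the species/sex comparisons.

Details, parameter defaults, and design rationale: `docs/methods.md`.

## Worked example

Run the bundled synthetic configuration (12 streams, 53 bears) end to
end:

```sh
bearsalmon -v run-all --config examples/synthetic.yaml --out demo
```

```
INFO bearsalmon.pipeline: stage ingest: {'streams': 12, 'escapement_rows': 780,
  'escapement_missing': 251, 'detections': 61, 'hair_samples': 54}
INFO bearsalmon.pipeline: stage impute: {'imputed_cells': 251,
  'loo_mean_cv_pct': 2.7192751836106437, 'loo_excluded': 0}
config 61dd7884411e; stages: ingest, impute, biomass, availability, diet, models, ...
```

251 of 780 escapement cells were missing and imputed; held-out observed
cells are reproduced with a mean log-scale CV of 2.7%. `demo/` then
contains a `report.json` plus one CSV per table. The diet stage
(`demo/tables/diet.csv`) gives each bear-year a posterior salmon
fraction:

```
bear_id,year,p_median,p_mean,ci_low,ci_high
G0001,2009,0.709,0.711,0.599,0.834
G0002,2009,0.937,0.931,0.830,0.996
```

and the model stage reproduces the diagnostic structure of the system.
For grizzly cortisol the top-ranked model is the consumption model with
a negative standardized coefficient (eating less salmon → higher
cortisol — nutritional stress):

```
# demo/tables/coefficients_grizzly_cortisol.csv
model_rank,model,term,estimate,se
1,consumption,consumption,-0.727,0.166
```

while for black-bear cortisol the individual and combined categories
carry most of the group-relative weight:

```
# demo/tables/group_weights_black_cortisol.csv
category,model,n_models,omega_pct
environment,productivity,5,12.9
individual,consumption+hormone,4,31.0
combined,additive_full,5,31.0
environment2,density_,4,25.1
```

(Values above are from this exact config and seed; they are
deterministic — running the command twice yields bit-identical tables.)

To analyse real data, point `source:` at a directory with
`streams.csv`, `escapement.csv`, `detections.csv`, and `hair.csv` in the
same column layout the simulator writes (`bearsalmon simulate` shows the
format), and supply real species masses, home-range areas, and mixing
model sources/discrimination in the config.

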