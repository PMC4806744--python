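# Methods

This note records the models implemented in `bearsalmon`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Scientific setting

Coastal grizzly (*Ursus arctos*) and black bears (*U. americanus*)
co-occur with spawning Pacific salmon, a nutritious but clumped and
seasonal food. Salmon abundance shapes both a bear's nutrition (how much
salmon it assimilates) and its social environment (how intensely bears
must compete at spawning streams). Hair collected non-invasively at snag
stations integrates diet tracers (δ13C, δ15N) and steroid hormones
(cortisol, testosterone) over the previous year's hair growth, so each
bear-year yields one row linking salmon availability, salmon consumption,
and hormone levels. The pipeline estimates, per bear-year: salmon
availability from escapement records and a home-range buffer; the salmon
fraction of assimilated diet from hair isotopes; and ranked regression
models relating hormones to environmental and individual predictors.

## Escapement imputation and validation

Spawner counts form a stream × species × year array with roughly 30% of
cells missing. Missing cells are filled with a two-way additive model on
the log(count + 1) scale,

    log(count_ijy + 1) ≈ α[stream i, species j] + γ[species j, year y],

fitted by alternating row/column means on observed cells only (the
least-squares solution for this model class), iterated until the largest
parameter change is below 1e−8. The year anomalies γ are shared across
streams within a species and mean-centred per species, so a stream's
missing year is predicted from the stream's own level plus the regional
year signal. Imputed counts are `round(exp(α+γ) − 1)` clamped at zero;
observed cells are never altered and imputed cells carry a provenance
flag. log(count + 1) rather than log(count) admits zero escapements.

A year column with no observed stream carries no regional signal; it
falls back to the mean anomaly (γ = 0) with a logged warning. A stream ×
species stratum with no observations at all cannot be anchored and raises
a named "unimputable stratum" error.

Validation is leave-one-out: each observed cell is removed, the model
refitted, and agreement between observed and predicted summarised on the
log scale by the two-value coefficient of variability,
CV = 100 · sd(obs, pred) / mean(obs, pred), reported per cell and as a
mean. For a pair, sd(obs, pred) = |obs − pred|/√2. The mean CV is 0 for
exactly log-additive tables and rises monotonically with observation
noise; it is the package's analogue of the field-data agreement statistic
reported for this kind of imputation.

Biomass per stream-year is Σ_species count × mass (kg/fish), with
biomass density B/L (kg per km of spawning reach) retained for
reporting. Species masses are config inputs (defaults are round
literature-scale values: pink 1.8 to chinook 9.1 kg).

## Salmon availability

Each detection is the anchor of a square lattice of candidate circular
buffers whose radius r = √(area/π) matches the largest species/sex
MCP-style home-range estimate (config input). The default lattice
spacing is r/4; of the 49 lattice points within distance r of the
detection, the 40 nearest become candidate centres (ties broken by x
then y offset, all keys exact integers, so construction is
deterministic). Because every centre offset is ≤ r, every candidate
buffer contains the detection. A spacing of r/3 would leave only 29
lattice points within range, too few for a 40-buffer grid, which is why
r/4 is the default; spacing is config-exposed.

A stream is inside a buffer iff its point location is within the radius
(distance < r; streams are treated as points since no reach geometry is
available). Hair sampled in spring of year y records the previous
growth season, so the growth year is t = y − 1; each buffer is scored by
B10 (mean total biomass over t−10 … t−1), and the buffer with maximal
B10 — across all detections of that bear-year — is selected, on the
assumption that bears position their ranges to maximise access to
salmon. Ties go to the candidate nearest its own detection, then to the
lowest detection index. The selected buffer also yields Bt (growth-year
biomass) and Bt1 (the year before). Buffer sums use total biomass B, not
density B/L; density is kept for reporting only.

The triplet (B10, Bt, Bt1) is strongly collinear, so a PCA of the
correlation matrix of the log(x+1) triplet provides two orthogonal,
mean-zero axes: axis 1, "watershed productivity," is sign-oriented to
correlate positively with log(B10+1); axis 2, "salmon availability," to
correlate positively with log(Bt+1) − log(B10+1), i.e. the growth-year
deviation from the long-term level.

## Diet from stable isotopes

A two-source (salmon, plants) two-isotope (δ13C, δ15N) mixing model with
MixSIR-form uncertainty propagation gives, for salmon fraction p,

    mean_j(p) = p(μ_sj + λ_sj) + (1−p)(μ_pj + λ_pj)
    sd_j(p)²  = p²(σ_sj² + τ_sj²) + (1−p)²(σ_pj² + τ_pj²) + ε_j²

with source means/SDs μ/σ, trophic discrimination means/SDs λ/τ, and a
residual SD ε_j, all in ‰ and all config inputs (the defaults are
synthetic, plainly labelled — real source and discrimination values must
be supplied by the user). With two sources the posterior over p is
one-dimensional, so the primary engine is exact quadrature on a uniform
grid (default 1001 points) with a uniform (Dirichlet(1,1) marginal)
prior: log-likelihoods are shifted by their maximum before
exponentiation (no underflow for extreme consumers), the density is
normalised by the trapezoid rule, and the median and central 95%
credible interval are read off the trapezoid CDF by linear
interpolation. A reflecting random-walk Metropolis sampler is included
only as an independent cross-check; it agrees with the grid mean within
Monte-Carlo error. Because the synthetic generator draws isotope noise
from the model's own sd_j(p), posterior intervals are calibrated by
construction on synthetic data; calibration on real data depends on the
supplied source/discrimination values, which the tests cannot establish.

## Hormone model selection

Analysis rows are male bear-years (female samples are too few for
modelling, as in the motivating study design). Rows extreme in either
raw hormone (|z| > 2, mean and sample SD computed once on the full
vector, no iteration) are excluded before transformation. Consumption
(a proportion) is arcsine-square-root transformed; hormones are
ln-transformed for black bears and negative-reciprocal transformed for
grizzly bears, whose distributions are more skewed; continuous variables
are standardized to mean 0, SD 1; year enters as 0/1 dummies (first
sampling year as reference) and bear-density stratum as a 0/1 indicator.
Collinearity screening reports pairwise Pearson correlations and
VIF_j = 1/(1 − R²_j); perfect collinearity yields an infinite VIF with a
flag rather than an exception.

Candidate models are ordinary least squares fits grouped a priori into
environment (productivity/availability), environment-2 (year, density;
only when those covariates exist), individual (consumption, the other
hormone), and combined categories, each including an intercept-only
model. Interaction models deliberately omit one main effect relative to
the full additive combined model, so no candidate is a strict superset
of another's terms — richer-by-chance fits cannot crowd a true additive
model out of the top set. Sets are fully user-overridable.

Ranking uses AICc = −2 log L + 2k + 2k(k+1)/(n−k−1) with k counting
coefficients plus one for the residual variance; Δ = AICc − min AICc;
Akaike weights w_i ∝ exp(−Δ_i/2); the top set is Δ ≤ 2 (the ≤ convention
is a config constant). Models with n − k − 1 ≤ 0 are dropped with a
warning; a zero-residual fit is flagged degenerate rather than ranked by
an unbounded likelihood. Group-relative weights divide each category's
top-model weight by the sum over categories' top-model weights, reported
in percent with the category's model count. The union ranking counts
each distinct term set once even if it appears in several categories.

Distributional comparisons (species × sex, per variable) use Wilcoxon
rank-sum tests in the Mann-Whitney convention, W = midrank sum of sample
1 minus n₁(n₁+1)/2: exact enumeration when n₁+n₂ ≤ 12 with no ties,
otherwise the tie-corrected normal approximation with continuity
correction. Families of comparisons are Holm-Bonferroni adjusted
(step-down, adjusted_(i) = max_{j≤i}(m−j+1)p_(j) capped at 1) with the
family size m recorded. Equality of variances uses the two-sided F ratio
s₁²/s₂² with df (n₁−1, n₂−1).

## The synthetic study generator

The generator emulates the study conditions end to end with known latent
truth. Streams are uniform in an abstract 60 × 60 km planar region (no
geodesy — the mathematics is location-free); reach lengths are
log-normal (median 1 km). Escapement is log-scale with per-stream-species
levels (between-stream SD 0.8 around species levels spanning pink ≈ e^9.2
down to chinook ≈ e^5.5 fish), shared per-species year anomalies
(SD 0.5), cell noise (SD 0.3), and 30% missingness at random — the rate
reported for coastal escapement databases. A stream-trend toggle
(default off) deliberately misspecifies the imputation model class for
robustness experiments.

Consumption follows the field's two shapes: grizzly saturating,
p(a) = 0.9·a/(a + 25 000 kg) (plateau near 0.9: most grizzly bears
assimilate > 80% of yearly protein from salmon at decent availability);
black Ricker, p(a) = 0.55·(a/a_pk)·e^(1−a/a_pk) with a_pk = 200 000 kg
(peak below 0.7, declining at very high biomass). Individual jitter
(SD 0.12 grizzly, 0.06 black; clipped to [0, 0.995]) represents
dominance-driven spread in intake at a given availability — wide in
grizzly bears, whose consumption scatters broadly at fixed biomass.

Stress follows the conceptual availability model. Nutritional stress is
N(x) = e^(−x/a_n) with x = a·(p_true/p_curve(a)) — availability scaled
by the bear's relative consumption, so a bear eating proportionally less
than its availability predicts experiences the nutrition of a poorer
site; at the population level N declines exponentially with
availability, vanishing when salmon are super-abundant. Social stress is
the Ricker hump S(a) = (a/a_s)·e^(1−a/a_s), peaking at intermediate
availability where competition is most intense and vanishing at both
extremes. Log hormones are Gaussian linear predictors — exponentiation
produces the right-skewed positive scales seen in hair, which is what
makes the ln / negative-reciprocal transforms meaningful downstream:

    log C = c0 + w_nut·N + w_soc·S + ε_c
    log T = t0 + w_prod·(log1p B10 − log1p b10_ref)
            − w_avail·(log1p Bt − log1p B10)
            + w_dens·1[high density] + w_cross·(log C − c0) + ε_t

Species presets encode the two pathways: grizzly nutrition-dominant
(w_nut = 1.2 ≫ w_soc = 0.15, a_n = 100 000 kg) and black social-dominant
(w_soc = 1.1 ≫ w_nut = 0.2, a_s = 15 000 kg, low enough that most
sampled availabilities sit on the declining limb of S, giving the
negative cortisol-availability association). Baselines give grizzly
higher cortisol (e^c0 = 2.5 vs 1.5 pg/mg) and lower testosterone (1.5 vs
3.0 pg/mg) than black bears. Noise SDs are 0.2 (log cortisol) and 0.25
(log testosterone). The quantitative forms and all numbers above are
generator conventions, not field claims; every weight is overridable.

Bear-years: 54 grizzly males, 14 grizzly females, 59 black males, 9
black females by default, sampled in 2009–2011 with a 5% recapture
fraction (recaptured bears appear in two years and are treated as
independent rows downstream, as only a handful of recaptures cannot
support random intercepts) and a 15% chance of a second within-year
detection (exercising the best-location rule). Home ranges: 700/250 km²
(grizzly m/f), 120/60 km² (black m/f). A fast bear-level generator
(`generate_bear_observations`) skips the spatial machinery — B10
log-normal per bear (medians 200 000 kg grizzly, 60 000 kg black, SD-log
0.7; Bt, Bt1 deviate with SD-log 0.5) — and is used for replicated
parameter-recovery experiments.

What the generator does *not* emulate: within-season run timing,
movement, age/size covariates, >2 dietary sources, observation effort,
and harvest. Passing recovery tests therefore demonstrate that the
estimators are correct for data of this structure, not that the paper's
field estimates are right, and not that real mixing-model inputs are
well calibrated.

## Numerical choices and degenerate inputs

- Imputation convergence: max parameter change < 1e−8, cap 2000 sweeps.
- Grid posterior: ≥ 101 points enforced, default 1001; CDF inversion by
  linear interpolation; log-likelihood max-shift before exponentiation.
- Buffer candidate ordering uses integer lattice keys — no float ties.
- PCA requires ≥ 3 records and non-degenerate columns; eigenvalues are
  clipped at 0; an undefined orientation target (zero variance) leaves
  the sign unchanged.
- Outlier screen with zero SD excludes nothing; all-tied rank-sum
  samples return p = 1 with a flag; a zero-variance denominator in the F
  test returns an infinite statistic with a flag.
- Problem sizes in the verification suite (e.g. 100 bears per diet
  fraction, 100 replicates of n = 200 bears for recovery rates, 12-stream
  studies for end-to-end runs) were chosen as the smallest sizes at which
  the replicated rates are stable.

## Known limitations

- Single deterministic imputation; no uncertainty propagation from
  imputed counts into downstream stages (mirrors the original design).
- The diet model is strictly two-source Gaussian; no concentration
  dependence or informative priors.
- The candidate-model catalogue is a reconstruction; the original
  per-hypothesis tables are not public, so defaults aim at the category
  structure rather than an exact model list.
- Whether outlier SDs should be pooled or per-stratum is unspecified in
  the source design; the screen here is per species × response family,
  applied to both hormones jointly.
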