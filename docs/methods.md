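# Methods

This note documents the statistical model, the numerical choices, and
what the synthetic-data studies do and do not demonstrate.

## Data model and screening

A record is one δ15N measurement from one dated, geolocated specimen.
Screening applies six exclusion rules in a fixed order (C/N atomic ratio
outside [2.9, 3.6]/missing/unreliable; uncertain taxon; juvenile; cervid
antler or tooth; duplicate analysis; outside the 35–60°N, 10°W–30°E
window), and a record failing several rules is tallied under the first,
so per-rule counts are reproducible and always sum to input minus
retained. Duplicates keep the first occurrence in file order — the
compilation literature rarely states a tie rule, and first-in-file is
auditable. Screening is idempotent.

## Radiocarbon calibration and binning

Single-date calibration on a regular calendar grid (default 5 yr):
p(t) ∝ exp(−(y−μ(t))²/(2(σ²+σ_c(t)²)))/√(σ²+σ_c(t)²), with (μ, σ_c)
interpolated from a three-column calibration-curve table. The 95.4%
region is built by greedy highest-density cell selection and merged into
intervals. "Median of the 95.4% range" is ambiguous between the
HPD-restricted median and the full-posterior median; both are computed
and reported, and binning uses the HPD-restricted median. Bins follow the
seven climate-event intervals between 8,190 and 50,000 cal BP; a
boundary-valued median belongs to the bin in which it is the *younger*
limit (membership is `lower ≤ m < upper` on the cal BP scale, with
exactly 50,000 closing the oldest bin), so shared boundaries are assigned
exactly once. Context-dated samples never pass through calibration; they
take their declared bin or are excluded when insecure or unknown. No
reservoir corrections or sequence modelling are attempted.

## Spatial QC

Weights are inverse Euclidean distance computed directly on (lon, lat)
degrees — the same metric the interpolation model uses — row-standardized;
no distance cutoff is applied. Coincident points (identical to 1e-9°)
are first jittered by independent uniform offsets in a 0.1° box centered
on the point; the first member of each group keeps its coordinates. The
uniform law is a choice (a "jitter of about 0.1°" does not pin down a
distribution); it is seeded and recorded.

Local Moran's I uses m2 = Σz²/n (denominator n, not n−1) so the
additivity identity Σᵢ Iᵢ = n·I_global holds exactly against Global
Moran's I. Inference is by conditional permutation (999 draws by
default): the value at i is held fixed while the others are permuted
across the remaining locations; the two-sided pseudo p-value is
(#{|I*|≥|Iᵢ|}+1)/(n_perm+1). A permutation-moment z-score and an
analytic (total-randomization) z-score are both reported. Global Moran's
I carries the standard randomization-assumption variance. P-values are
FDR-adjusted (Benjamini–Hochberg, via statsmodels); "significant at the
0.95 level" is read as p_FDR < 0.05. Points with significantly negative
local I are spatial outliers and are removed before aggregation.

Note that a Local-Moran outlier is a point *dissimilar from its
neighbours relative to the global mean*: an extreme value planted inside
a region lying on the same side of the mean registers as a cluster
member, not an outlier. The planted-outlier study therefore plants a low
value inside a high region of a latitudinally structured field, which is
also the failure mode that matters for δ15N compilations (a misdated or
ecologically aberrant sample contradicting its neighbourhood).

## Two-step geostatistical model

**Aggregation.** Per site × bin: mean, sample variance (n−1 denominator,
missing for single-observation sites) and count, with jittered
coordinates averaged per site.

**Dispersion model.** v_i ~ Gamma(shape k_i=(n_i−1)/2, mean φ(s_i)),
log φ = β_d0 + u_d(s) + b_d, u_d a Matérn GP, b_d iid Gaussian. The
shape is fixed at (n−1)/2, the exact sampling distribution of a
normal-sample variance (an estimated-shape option is deliberately not
offered; the residual model already absorbs extra-Gamma spread through
b_d). Fitting is Laplace-approximated *restricted* maximum likelihood:
the covariance parameters maximize the Laplace marginal with the
intercept integrated out together with the latent field (flat prior),
and the intercept is then estimated by marginal maximum likelihood at
the restricted covariance estimates. During development the plain joint
maximization (intercept in the outer optimizer alongside the variances)
showed the familiar ML downward bias in the variance parameters and a
biased intercept on recovery simulations; the restricted form removed
both. The intercept's standard error comes from the joint
(intercept, field) Hessian, so it includes the spatial field's own
uncertainty; it is conditional on the covariance estimates, which makes
it mildly anti-conservative when the spatial variance collapses to the
boundary.

**Mean model.** ȳ_i = x_iᵀβ + u(s_i) + b_i + ε_i with u ~ GP(0, σ²_u ·
Matérn(ν, ρ)), b iid N(0, σ²_b) (the nugget, indexed by site), and
ε_i ~ N(0, φ̂_i/n_i) *fixed* at the dispersion-model predictions scaled
as the variance of a mean of n_i observations (`residual_scale="raw"`
uses φ̂ unscaled; the per-mean scaling is the default because ȳ_i is an
average). Variance parameters maximize the REML objective
−½[log|Σ| + log|XᵀΣ⁻¹X| + rᵀΣ⁻¹r] with β profiled by GLS; standard
errors come from (XᵀΣ⁻¹X)⁻¹. Sites lacking a dispersion fit (single
observations) receive the spatial BLUP of the log-dispersion field
without a site effect, so a site far from all data tends to
exp(β̂_d0) — the response-scale plug-in, not the lognormal mean; the
distinction is documented because it changes predictions at remote sites
by the factor exp(σ²/2).

**Matérn.** C(d) = 2^(1−ν)/Γ(ν) · (d/ρ)^ν · K_ν(d/ρ), evaluated in log
space against closed-form checks at ν = 1/2 and 3/2. Distances are
Euclidean in degrees on (lon, lat), deliberately uncorrected for
meridian convergence: the QC weights, the fitted covariance and the
prediction grid then share one geometry, and at the 35–60°N study
window the anisotropy this induces is absorbed by the estimated range.
ν is estimated over [0.1, 5] by default and can be fixed (`fix_nu`);
the simulation studies fix ν = 0.5 so the generating and fitted families
coincide and runtimes stay modest. Optimization is multi-start (3 seeded
starts by default) bounded L-BFGS-B on log-transformed parameters,
objective tolerance 1e-9; log-variances are bounded in [−20, 10],
log-range in [log 1e-3, log 1e3].

**cAIC.** Model comparison uses the conditional AIC:
−2·log f(y | β̂, û, b̂) with per-site residual variances φ̂_i/n_i, plus
twice the effective degrees of freedom ρ_eff = trace of the hat matrix
mapping y to the conditional fitted values (A + Σ_re Σ⁻¹(I−A), with A
the GLS projection) plus one per estimated covariance parameter. In the
degenerate limit σ²_u = σ²_b = 0 this reproduces the AIC of the weighted
linear model exactly. Ties rank by fewer fixed effects. cAIC values are
implementation-specific (the effective-df convention differs across
mixed-model software); only ranking behaviour is asserted, never
particular values.

**Candidate set.** Twelve fixed-effect structures — the empty model; MAT;
MAP; MAT+MAP; MAT+MAP+MAT:MAP; temp.warm; precip.warm; precip.cold; and
the three pairwise/one triple combination of the warm/cold-quarter
variables — all with spatial + site random effects.

**Prediction.** Universal kriging at each unmasked grid cell:
prediction x₀ᵀβ̂ + c₀ᵀΣ⁻¹(y − Xβ̂) with c₀ the spatial covariance to
the data sites (the site effect contributes only at cells coinciding
with a data site); variance σ̂²_u + σ̂²_b − c₀ᵀΣ⁻¹c₀ +
g₀ᵀ(XᵀΣ⁻¹X)⁻¹g₀, g₀ = x₀ − XᵀΣ⁻¹c₀. Fixed-effect uncertainty is
included; the sampling variance of a hypothetical new observation is
not (the surface maps the site-level mean process). With zero nugget
and zero residual variance the surface interpolates the site means
exactly and has zero variance there. Default grid 0.5°, matching the
covariate resolution; masking only via a user-supplied 0/1 raster.

## Covariates

Five bioclimatic variables (MAT, MAP, temp.warm, precip.warm,
precip.cold), one raster per variable per simulation time step, plus one
time-invariant elevation layer (sea-level and isostatic change are not
modelled). Each bin maps to a fixed time step (EH→11 ka ... EOIS3→42 ka).
Extraction is bilinear by default — 0.5° cells are coarse relative to
site-coordinate precision — with nearest-neighbour by flag; missing
neighbours propagate to missing, and affected site×bin rows are flagged,
never silently dropped. Sites with missing covariates are excluded from
fixed-effect fits but retained for the random-effects-only model.
Raster I/O is netCDF (scipy backend) and long-format CSV.

## Synthetic data

The generators emulate the statistical regime of a continental
late-glacial collagen compilation: ~25–150 sites per bin scattered over
the study window with ~10% coincident coordinates, 1–30 observations per
site (1 + Poisson), site means centred near 4‰ with SD near 2‰, a Matérn
mean field with range about a quarter of the window, a weaker Matérn
log-dispersion field, and injectable screening violations at configured
rates. Climate rasters combine a latitudinal gradient with unit-SD broad
(~3°) and variable-specific fine (~0.75°) smooth fields at physical
amplitudes; the fine components keep the five covariates distinguishable
at sub-regional scale, as real climate fields are, while leaving MAT and
temp.warm strongly correlated overall (r ≈ 0.95 across the window) —
without them, any covariate effect would be perfectly confounded with
the spatial random effect and selection tests would be vacuous. The
synthetic calibration curve is a strictly monotone trend (slope 0.95)
plus bounded sinusoidal wiggles and a slowly growing error column.

What passing synthetic studies shows: the estimators are consistent and
approximately calibrated, selection prefers true structure, and the
pipeline reconstructs latent surfaces under its own assumptions. What it
does not show: robustness to species-composition shifts across space,
taphonomic or inter-laboratory biases, non-Gaussian residuals, dating
-error-induced bin misassignment beyond what calibration noise induces,
or covariate error in palaeoclimate simulations.

## Study sizes used by the validation suite

Chosen to exercise the published regime on a single CPU: recovery, 50
simulations × 100 sites; selection, 50 simulations × 100 sites × 12
models (dispersion estimated in-loop); outlier recall, 50 seeds × 60
points × 999 permutations; isoscape-truth correlation, 25 seeds × 150
sites on a 2° evaluation grid; the end-to-end run, 25 sites/bin over
all 7 bins. Measured rates at the frozen seeds: mean-intercept 95% CI
coverage 0.90; dispersion-intercept within 2 SE 0.90; a MAT-containing
model ranked best in 74% of effect simulations (a temperature-containing
one in 92% — MAT and temp.warm are near-collinear by design); the empty
model within ΔcAIC ≤ 2 of the best in 96% of null simulations; planted
outliers removed in 94%; isoscape-truth r ≥ 0.7 in 92% (median r 0.81).
Borderline quantities vary noticeably across seed batches — in repeated
runs with different master seeds the dispersion-intercept 2-SE rate
ranged about 0.82–0.90, the effect-selection rate 0.58–0.74, and the
isoscape r ≥ 0.7 rate 0.64–0.92. That spread is inherent to 25–50
replicate studies of boundary-sensitive quantities; thresholds were set
a priori and the suite's seeds are fixed, so its results are exactly
reproducible.

## Known limitations

- The spatial confounding between smooth covariates and the Matérn
  random effect is real and by design visible: with strongly collinear
  covariates (MAT vs temp.warm), cAIC cannot reliably name *which*
  temperature variable acts, only that one does.
- The dispersion-intercept SE is conditional on the covariance
  estimates and under-covers slightly when σ²_u is estimated at the
  boundary.
- Degree-based distances make the covariance mildly anisotropic in
  kilometres; a haversine option would change fitted ranges but not the
  pipeline's structure.
- Calibration is single-date only; multi-date Bayesian sequence models
  and reservoir offsets are out of scope.
- cAIC values are not comparable across mixed-model implementations;
  only within-run rankings are meaningful.
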