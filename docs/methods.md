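# Methods

## Analysis model

### Scale

Array methylation arrives as beta values β ∈ [0,1] (fraction methylated).
All modelling happens on the M scale, M = log2(β/(1−β)), which is closer to
homoscedastic and unbounded; beta values are retained for display and for
the variability filter of the QC stage. `beta_to_m` clips β into
[ε, 1−ε] with ε = 1e-6 before the logit so fully (un)methylated probes stay
finite; ε is far below array noise and the round trip `m_to_beta∘beta_to_m`
is exact away from the clip.

### Per-probe linear models and variance moderation

For probe g with M-values y_g (length n) and design X (intercept, phenotype
of interest, adjustment covariates), OLS gives β̂_g, residual variance s²_g
on d_g = n − rank(X) degrees of freedom, and the unscaled standard deviation
u = sqrt[(XᵀX)⁻¹]_jj of the phenotype coefficient. The hierarchical model
places a scaled inverse-chi-square prior on the true variances: 1/σ²_g ~
χ²_{d₀}/(d₀s₀²). The posterior-mean variance is

    s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g),

and t̃_g = β̂_g/(u s̃_g) has a t distribution on d₀ + d_g df under the null
(standard normal when d₀ = ∞). Prior estimation matches the first two
moments of e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2): the excess of the sample
variance of e_g over mean ψ′(d_g/2) identifies ψ′(d₀/2), solved by a Newton
iteration on the trigamma function (`trigamma_inverse`, relative tolerance
1e-8, asymptotic starts 1/√y for y > 1e7 and 1/y for y < 1e-6); s₀² follows
from the mean of e_g. Non-positive excess spread means the log-variances are
no more dispersed than pure chi-square sampling predicts, so d₀ = ∞ and
s₀² = exp(ē) (which carries the log-scale bias-correction factor
(d_g/2)/exp(ψ(d_g/2)), ≈ 1.011 at d_g = 89). d₀ = 0 is accepted as the
no-moderation limit and reproduces the ordinary t exactly. Probes with
s² = 0 (perfect fits) are excluded from prior estimation with a warning.

Model presets mirror the analysis plan: DST non-suppression adjusts for
hypersexuality and baseline cortisol; the TSH/T4 ratio for hypersexuality
and IL-6; cortisol and ACTH (baseline and post-DST) are unadjusted. Samples
missing any model variable are dropped complete-case with the count logged.
Binary phenotypes enter as 0/1 covariates in the probe-wise model (not as a
group-means parametrisation), matching the regression formulation the
presets encode.

### Multiple testing

Per-probe p-values get Benjamini–Hochberg step-up adjustment (delegated to
`statsmodels.stats.multitest`, cross-checked in the tests against an
independent step-up oracle). Transcript-level Bonferroni multiplies by the
number of transcripts tested, i.e. those with ≥ 1 annotated probe in the
panel — the multiplier is recorded on the result table.

### Transcript enrichment

k = #(probes with raw p < α) out of n annotated probes is referred to
Binomial(n, α), α = 0.05, ignoring effect direction. The two-sided
convention is minimum-likelihood (sum of P(X = x) over outcomes no more
likely than observed), matching the exact-test convention of the standard
statistical environments; `--sided greater` gives the one-directional tail.
For the fully-significant transcripts that drive the headline results
(k = n) the two conventions coincide. Raw, not FDR-adjusted, p-values are
thresholded. Probes annotated to multiple transcripts count once per
transcript. The test treats probes as independent; correlated neighbouring
probes make it anti-conservative, a known limitation.

### Expression correlation (eQTM)

Probes of a transcript are averaged per sample on the M scale, then
correlated with the gene's normalized expression by (a) Pearson r with the
two-sided t-based p, and (b) MM-type robust simple regression: candidate
lines through point pairs (exhaustive up to 600 pairs, then a fixed-seed
subsample, so the estimate is deterministic), each scored by the
50%-breakdown bisquare M-scale (c = 1.5476) of its residuals; the best
candidate seeds bisquare IRLS at 90% normal efficiency (c = 3.8827) with
the S-scale held fixed. Wald p-values use the usual M-estimator asymptotic
covariance s²·E[ψ²]/E[ψ′]²·(XᵀX)⁻¹ on n−2 df. Robust-regression software
differs in its ψ family and efficiency defaults, so slopes — not exact
p-values — are the comparable quantity across implementations. Convergence
failure raises; the cohort-level driver records it as a missing robust
result rather than silently reporting an unconverged fit. On clean Gaussian
data the estimator tracks OLS closely (within sampling noise at 90%
efficiency) but exact OLS equality holds only for degenerate (exact-line)
data.

### Post-hoc interaction models

Linear: OLS of methylation on two binary factors and their product; on
balanced designs the interaction coefficient equals the cell-means contrast
(μ₁₁−μ₁₀)−(μ₀₁−μ₀₀), which the tests verify exactly. All four cells must be
populated. Logistic: IRLS (max 50 iterations, deviance tolerance 1e-10)
with Wald p-values; separation is detected by a diverging coefficient norm
(> 1e3), a singular weighted design, or a deviance collapsing to zero, and
raises `SeparationError` instead of returning a diverged fit.

### Cohort statistics and covariate selection

Continuous variables pass through a Shapiro–Wilk gate (per group, α = 0.05;
the gate's α is a package choice, recorded here): both groups normal →
Welch two-sample t; otherwise Kruskal–Wallis. Fully tied data short-circuits
to p = 1. Binary traits use the chi-squared test of independence with Yates
continuity correction — the default of the reference environment and what
reproduces the printed p = 5.78E-02 for the 17/20-vs-43/73 hypersexuality
table; the uncorrected statistic is available by flag. Covariate screening
is classic greedy forward selection by extra-sum-of-squares F tests at
p < 0.10, deterministic name tie-break, with the complete per-step
evaluation trace retained (step-1 rows give the each-candidate-alone
reading). Binary outcomes use the same linear-model ANOVA (a linear
probability model), matching the screening procedure the presets assume; a
previously accepted covariate is not re-tested after later additions.

### Sample QC

Probes with per-probe beta SD above 0.2 (interpreted as a variability
inclusion filter; the package's reading of the published "threshold of
0.2") enter a PCA of the probe-centered sample matrix. A sample is flagged
when its PC1 score falls outside mean ± z·SD with z = Φ⁻¹((1+0.95)/2) =
1.96 — a reproducible stand-in for the visual PC1 inspection it replaces.
The report carries the PC1 variance share, per-sample scores and the probe
count used. Under a pure-noise null this rule flags ≈ 5% of samples by
construction; widen `ref_range` for a stricter call. A generic
`regress_out` hook removes supplied per-sample covariates (e.g. cell
fractions) from M-values probe-wise, preserving probe means;
reference-based cell-type deconvolution is out of scope.

## Synthetic cohort: what it emulates, what it does not

Defaults are the study conditions: 20 cases vs 73 controls; 76 candidate
probes over nine transcripts of the six panel genes, including a 2-probe
*NR3C1* transcript (AJ877169) and a 14-probe *CRHR2* transcript (EU012442)
so both enrichment patterns that matter are resolvable; binary covariates at
the published prevalences (hypersexuality 85%/58.9%, depression
15%/8.2%); continuous covariates at the published group means/SDs (baseline
cortisol 515.2 (147.2) vs 458.5 (133.5) nmol/L, IL-6 2.03 (0.12) vs 2.30
(0.98) ng/L, TSH/T4 0.017 (0.0099) vs 0.023 (0.0233), etc.).

Methylation is logit-normal: per-probe baseline M ~ U(−3, 3), plus the
planted per-probe M-shift for cases, plus N(0, noise_sd) residuals,
inverse-logit2 to betas. noise_sd defaults to 0.5 M-units, a typical
within-group spread for promoter-window array probes. Effects are additive
on the M scale — the scale the analysis fits — so planted effect sizes are
directly interpretable. Background annotation rows (non-panel genes, wider
TSS range, per-probe noise SD drawn U(1, 3) M-units with mid-range
baselines) exercise the candidate filter and give the variability-filtered
QC stage probes to work with, standing in for the genome-wide variable
probes a real array provides. The paired expression generator draws one
expression profile per gene and per-transcript latent factors at the
configured correlation ρ; probe noise (SD 0.3 M) attenuates the realised
transcript-average correlation slightly below ρ.

Not emulated: probe-type chemistry and IDAT intensities, batch structure,
cell-type composition, probe–probe spatial correlation within a transcript,
non-normal M-value tails, and covariate–methylation confounding beyond what
the planted group effect induces. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the declared
generative model — not that real-array artefacts are handled.

## Numerical choices

- Beta clip ε = 1e-6; matrix containers reject duplicated probe/sample ids
  and out-of-range betas at construction.
- `trigamma_inverse`: Newton, relative tolerance 1e-8, closed-form
  asymptotic branches beyond y ∈ [1e-6, 1e7].
- MM regression: elemental-pair S-stage (exhaustive ≤ 600 pairs, fixed-seed
  subsample above), IRLS stop on step < 1e-10 (relative) or bisquare
  objective stalled below 1e-12 — the objective criterion guards against
  machine-precision dithering at small n; hard failure after 200 iterations.
- Logistic IRLS: linear predictor clipped at ±30 inside iterations purely
  for overflow safety; separation raises before results are reported.
- Forward selection: perfect fits (RSS = 0) are treated as p = 0; singular
  designs name the offending covariate.
- Ties in the enrichment two-sided tail use a 1+1e-12 relative slack when
  enumerating outcomes of equal likelihood (tests only; the implementation
  delegates to the exact test of scipy).

## Problem sizes used in validation

Calibration and recovery checks run at the study's own scale (76 probes,
20 vs 73 samples): 500 null-cohort replicates for type-I calibration, 50
seeded replicates for planted-transcript recovery, G = 5000 probes for
variance-prior recovery, 300–2000 replicates for the smaller Monte-Carlo
rate checks. These sizes give standard errors comfortably inside the
asserted bands while keeping the default suite quick to run.

## Known limitations

- The binomial enrichment ignores intra-transcript probe correlation
  (anti-conservative on real arrays).
- The robust-regression p-value rests on an asymptotic covariance; at
  n = 10 it is indicative, not exact — slopes are the stable quantity.
- The PCA outlier rule is a reproducible convention, not a validated
  replication of visual QC decisions.
- Genome-wide scale (≫ 10⁴ probes) is outside the design target; the
  per-probe fits are vectorised but prior estimation and enrichment assume
  candidate-panel sizes.
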