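# Methods

## The problem the package models

Earlier puberty is widely associated with adult obesity and cardiometabolic
risk. The causal question is whether puberty timing *drives* those outcomes
or merely *marks* pre-pubertal adiposity, which both advances puberty and
tracks forward into adulthood. Mendelian randomisation (MR) uses genetic
variants as instruments for the exposure, but variants associated with
puberty timing overlap heavily with adiposity genetics, so the core MR
assumption (instruments affect the outcome only through the exposure) is in
doubt. The package implements the analysis pattern designed for exactly
this situation: a time-sensitive exposure allows (i) adjustment for a
confounder measured *before* the exposure completes, and (ii) negative-
control outcomes measured before the exposure, on which no valid instrument
set can show an effect.

## Structural model of the synthetic cohorts

For effect-allele dosages `d_j ~ Binomial(2, maf_j)` (Hardy–Weinberg,
independent SNPs unless a Gaussian-copula LD structure is requested):

    C    = i_C  + Σ_j γ_j d_j + ε_C                  childhood confounder (kg/m²)
    M    = i_M  + Σ_j α_j d_j + δ·C + ε_M            exposure (age, years)
    Y8   = i_8  + θ·C + Σ_j π_j d_j + ε_8            pre-exposure outcome
    Y18  = i_18 + β·M + θ·τ·C + Σ_j π_j d_j + ε_18   post-exposure outcome

with Gaussian noise throughout. `γ` routes instrument effects through the
confounder (the pathway that breaks exclusion), `π` is horizontal
pleiotropy, `δ` the confounder→exposure effect (years per kg/m²), `θ` the
confounder→outcome effect, and `τ` the confounder's raw tracking slope into
its adult re-measurement. `Y8` carries no `M` term — it is temporally prior
to the exposure, which is what licenses its use as a negative control, and
the cohort table's declared time ordering (`attrs["time_order"]`) is
enforced by `run_negative_control` and by the pre-exposure adjustment
modes. Two-sample summary statistics come from two cohorts drawn from
*named sub-seeds* of one seed (disjoint streams, no sample overlap), with
per-SNP univariable OLS in each. An option floors the reported exposure to
whole years (self-report rounding) while outcomes respond to the latent
value, so rounding-induced attenuation can be quantified separately; no
default measurement-error SD is claimed for recall-based exposures.

## Presets and their parameter choices

**`menarche` (cohort-scale scenario).** Built from published moments of the
motivating study population, with a deliberately chosen ground truth of
**β = 0** — every apparent exposure→outcome effect is confounding:

| quantity | value | why |
|---|---|---|
| exposure mean, SD | 12.4 y, 1.1 y | observed menarche distribution |
| score R² on exposure | 10.6 % (F ≈ 217 at n = 1,831) | published instrument strength; 100 SNPs, effects scaled to hit it |
| share of marginal SNP effect through C | 20 % | with δ = −0.26 gives a negative-control effect θ·(0.2/δ) ≈ −0.77 kg/m², the size reported in this design's motivating analysis |
| δ (C→M) | −0.26 y per kg/m² | published reverse-MR estimate |
| BMI-score R² on C | 3.44 % (F ≈ 113 at n = 3,171) | published BMI-instrument strength; 50 γ-only SNPs |
| sd(C) ≈ 1.95, τ = 1.76, sd(Y18) total ≈ 4.3 | tracking correlation 0.8 with childhood/adult SDs 2.0 / 4.3 | reproduces the ~−1.4 kg/m² unadjusted MR estimate and its collapse on adjustment |

Sex, assessment age and maternal education are carried as inert covariates:
they exercise the adjustment interfaces without entering the structural
equations, so adjusted and unadjusted truths coincide for them.

**`validation`.** Estimator-consistency scenario: 8 independent SNPs with
per-allele effects 0.15–1.25, no confounding or pleiotropy, true β = 0.5,
exposure noise SD 0.5, outcome noise SD 4. The instruments are deliberately
strong (high synthetic heritability): with n = 5,000 per sample, the
finite-sample ("weak instrument") attenuation of regression-based summary
estimators scales with `se_x²/var(β_x)`, and these choices keep that bias
an order of magnitude below per-replicate sampling error. This is a
validation design, not a realism claim.

**`heterogeneity`.** 20 SNPs, β = 0.3, outcome noise SD 5 (keeping
`β²·se_x²` negligible against `se_y²`, so Cochran's Q with 1/se_y² weights
is calibrated). Pleiotropy variants: `balanced` alternates ±spread with
zero mean; `directional` alternates around mean 0.35 outcome units per
allele. The alternating pattern is uncorrelated with instrument strength
(the InSIDE condition MR-Egger assumes).

**`breakdown`.** 10 equal-strength SNPs (equal inverse-variance weight), 4
of them (40 % of weight) invalid via pleiotropy that moves their Wald
ratios from the true 0.3 to 1.0 — the weighted median's breakdown test.
With 40 % invalid weight the weighted median sits at the upper edge of the
valid cluster, so a small positive finite-sample bias (well inside its
bootstrap SE) is expected and observed; IVW, by contrast, is pulled toward
the invalid ratios by the full invalid weight share.

## Estimator details and numerical choices

- **Robust SEs** are HC1 (the common "robust standard errors" default);
  2SLS uses the correct IV sandwich, with residuals formed from observed
  (not fitted) regressors and covariates present in both stages. With one
  instrument and no covariates 2SLS equals the Wald ratio identically.
- **CIs** are `β ± 1.96·SE` throughout, except MR-Egger, whose SEs carry an
  estimated residual scale and therefore use the t(J−2) critical value (and
  t-based p-values) — with few instruments the normal approximation
  undercovers materially.
- **Weak instruments**: first-stage F (partial F given covariates) is
  attached to every 2SLS record; F < 10 raises a warning, never an error. A
  noise-free instrument (score ≡ exposure) degenerates cleanly to OLS; a
  zero-variance score is a hard error.
- **IVW** reports both the fixed-effect SE and a multiplicative
  random-effects SE (inflated by √(Q/df) when Q/df > 1, the default);
  Cochran's Q uses the standard 1/se_y² weights.
- **Weighted median**: interpolation at 50 % of cumulative normalised
  inverse-variance weight over ordered ratios; SE by parametric bootstrap
  (default 1,000 draws, fixed seed) resampling (β_x, β_y) from their
  reported sampling distributions.
- **Harmonisation**: outcome effects aligned to the exposure's effect
  allele, with strand-complement resolution; A/T and C/G SNPs with EAF in
  [0.42, 0.58] in either study are dropped as ambiguous (a conventional
  window; configurable). Proxy-SNP substitution is represented only as the
  `dropped_missing` accounting category — no LD reference panel is consulted.
- **LD pruning** is greedy by ascending p-value with defaults r² < 0.01
  within 10,000 kb. Ties in p break by SNP id for determinism.
- **Missing dosages** are mean-imputed per SNP (observed mean), keeping the
  per-individual SNP count stable; the imputation count is reported.
- **Multiple testing**: exact Bonferroni threshold α/n (0.05/33 ≈ 0.00152
  for the canonical 33-independent-tests setting); any rounding is
  presentation only, and corrected flags always imply nominal flags.
- **Scoring division** uses the number of SNPs actually scored (J_used),
  not the nominal weight-table length.

## What the tests do and do not show

The simulation scenarios validate the *estimators and the design logic*:
parameter recovery, CI calibration, negative-control detection of
through-confounder instruments, attenuation under pre-exposure adjustment,
heterogeneity-statistic calibration, and weighted-median robustness. They
run at reduced scale (replicate cohorts of 2,000–5,000 individuals and
8–150 SNPs; 50–1,000 Monte-Carlo replicates per property), sizes chosen so
each statistical property is measured with adequate Monte-Carlo precision.
The generator does not model genotyping error, imputation uncertainty, real
LD panels, family structure, selection into questionnaire response, or
non-Gaussian trait distributions — so passing tests certify the methods'
behaviour under the assumed causal structure, not the measurement quirks of
any real cohort. Real-data coefficient values from access-restricted
individual-level or consortium summary data are not reproduction targets;
the package reproduces the *mechanisms* (instrument strength, attenuation
pattern, negative-control signature) at matched scale.

## Known limitations

- Linear, homogeneous effects only; no non-linear MR, LIML/GMM, MR-PRESSO
  or mode-based estimators.
- One-sample 2SLS assumes the score is the only endogenous-relevant
  instrument column; over-identified multi-instrument sets beyond the
  two-score MVMR case are not exposed.
- Strand resolution for individual-level scoring is label-based (the
  synthetic data controls labels); real-data palindrome resolution by
  frequency is implemented only for summary statistics.
- The Egger intercept test's power statements hold under InSIDE-compatible
  pleiotropy as generated here; adversarial pleiotropy correlated with
  instrument strength is out of scope.
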