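# Methods

## Scope and model

`dietmeta` implements a stratified-then-pooled observational analysis.
Within each cohort c ∈ {HC, IBS, CD, UC} it fits ordinary least squares

    y_i = α + β_c x_i + γ' z_i + ε_i,      ε_i ~ N(0, σ²)

where y is a transformed microbial feature (arcsine-square-root taxon
proportion, log pathway abundance), a cluster centroid, or a
log inflammation marker; x is the dietary exposure; and z are the
covariates (age in years, sex as 0/1, log10 sequencing read depth, plus
total kcal/day for centroid and marker models). The per-cohort
estimates (β_c, SE_c) are pooled with fixed-effect inverse-variance
weights w_c = 1/SE_c²:

    β_meta = Σ w_c β_c / Σ w_c,   SE_meta = (Σ w_c)^(-1/2),
    z = β_meta / SE_meta,          Q = Σ w_c (β_c − β_meta)² ~ χ²(k−1).

p-values are BH-adjusted within a family (one exposure × all responses
of one kind; configurable to a single global family), and an
association is reported as significant only if FDR < 0.05 **and**
p(Q) > 0.05. The gate's logic: fixed-effect pooling is only meaningful
when the per-cohort effects are exchangeable, so heterogeneous pairs
are excluded rather than re-modelled — random-effects pooling is
deliberately not offered, because the gate-and-pool design answers a
different question (which associations are *shared* across disease
contexts) than a random-effects mean would.

Assumptions worth keeping in mind: linearity of the transformed
feature in the exposure, homoscedastic errors within cohort,
independence of subjects, and exposures measured without error (FFQs
are in truth noisy instruments; no measurement-error correction is
attempted).

### Exposure scaling

The printed model formulas leave exposure units open. By default every
exposure is z-scored within the cohort's complete cases
(`standardize_exposure=True`), so β is "transformed-feature units per
SD of intake" and comparable across foods with very different
consumption scales. Raw-unit exposures are available by switching the
flag off; pooling and gating are unaffected. Individual foods and
nutrients enter energy-adjusted (g/1000 kcal); cluster centroids enter
on the g/day scale with kcal as a covariate, mirroring the two ways
the analysis controls for total energy intake.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_depth` | 1e7 | reads | samples strictly below are removed; a sample at exactly 1e7 is kept ("below" read as strict) |
| `min_prevalence` | 0.10 | fraction | feature must be nonzero in ≥10 % of retained samples |
| `min_mean_abundance` | 1e-4 | proportion | taxa only (0.01 % relative abundance); interpreted as a *mean* because a max-based rule removes almost nothing |
| `grubbs_alpha`, `grubbs_max_iter` | 0.05, 5 | — | two-sided, iterative per feature; masks cells (set-missing) instead of deleting samples so per-cohort n is preserved |
| pathway pseudocount | half min nonzero, per feature | abundance | keeps log defined at 0 while holding features on comparable scales |
| `linkage` | complete | — | average and Ward available; cut heights are only meaningful jointly with the linkage, so both are always recorded in the manifest |
| cut heights | half the root merge height | distance | data-driven default; for the original FFQ/MetaPhlAn tables the documented cuts are 53 (food tree) and 0.8 (species tree) |
| `standardize_food_distance` | False | — | z-scores foods before the squared-Euclidean tree, making it co-consumption-driven (2(n−1)(1−r)) instead of scale-driven |
| `min_complete_cases` | 20 | subjects | per-cohort fits below this are flagged unusable and dropped from pooling (k is recorded) |
| `fdr_max`, `qp_min` | 0.05, 0.05 | — | both strict inequalities |
| frequency map | never 0, 1/month 1/30, 2–3/month 2.5/30, 1/week 1/7, 2–4/week 3/7, 5–6/week 5.5/7, daily 1 | days/day | the 7-level scale's conversion is not standardised anywhere; this midpoint convention is explicit and overridable |

## The synthetic generator

`simulate_cohorts` emulates the statistical structure the analysis
assumes, with every choice seeded and echoed into the truth table:

* **Cohorts.** Default sizes 872/223/205/124 (HC/IBS/CD/UC) with
  cohort-specific age means, sex ratios, smoking and statin rates in
  the ranges typical of IBD/IBS cohort studies.
* **Foods.** Zero-inflated log-normal: item i belongs to one of
  `n_food_blocks` contiguous blocks; its latent Gaussian is
  √ρ·F_block + √(1−ρ)·ε (ρ = `block_corr`), exponentiated with item
  medians e^2.5–e^3.5 g/day and log-sd 0.8, then zeroed with
  probability `zero_inflation` (structural non-consumers). The blocks
  are the ground-truth dietary patterns.
* **Energy.** kcal/day = 1200 + 700·(total intake / mean) + noise,
  so total energy is confounded with diet as in real FFQ data.
* **Read depth.** Log-normal, median 2×10⁷, σ chosen so ~10 % of
  samples fall below the 10⁷ filter and the depth stage is genuinely
  exercised.
* **Taxa.** Logistic-normal composition: Gaussian feature scores with
  covariate loadings on the log-ratio scale, softmax to proportions
  (rows sum to 1), detection limit 1e-5. A Dirichlet model was
  rejected because it cannot carry covariate/block covariance.
* **Pathways.** Log-normal abundances with covariate loadings and
  residual sd `noise_sd` (default 1.0 — a single food then explains at
  most ~20 % of a pathway's log-variance even for the strongest
  planted effect, which is already generous relative to real
  diet–microbiome effect sizes). A small fraction of cells
  (`pathway_low_rate` = 0.5 %) is scaled to ~1 % of typical abundance,
  mimicking near-detection-limit measurements; these give the Grubbs
  stage true low outliers to mask and keep the log-transform
  pseudocount far below typical values.
* **Planted effects.** β · (per-cohort multiplier) · x̃, added on the
  post-transform scale, where x̃ is the within-cohort z-score of the
  energy-adjusted intake among depth-passing subjects — exactly the
  regressor the association stage uses, so the generating coefficient
  is the estimand. For pathways (unbounded log scale) this is exact.
  For taxa the arcsine-sqrt scale is bounded on [0, π/2] and rows must
  re-close to 1, so large planted taxa effects are clipped and
  renormalised and recovered attenuated (roughly a third at β = 0.3);
  accuracy-critical recovery and coverage checks therefore plant on
  pathways.
* **Markers.** Fcal and CgA are log-normal, log-linearly tied to
  designated food-block mean intakes (the paper-gap here is real: no
  distributional detail exists for these markers, and log-normality is
  an assumption).
* **Covariate confounding.** Age/sex/log-depth effects enter every
  feature through per-feature Gaussian loadings scaled by the
  configured coefficients. The kcal coefficient on microbial features
  defaults to 0: the taxon/pathway models do not adjust for kcal
  (energy control is via the density exposure), so a direct
  kcal→feature path would make the generator's "null" pairs not null.
  Setting it nonzero is how one demonstrates energy confounding.

What the generator does **not** emulate: measurement error in the FFQ,
compositional coupling between pathways, phylogenetic correlation
between taxa, longitudinal structure, batch effects, and missing
metadata. Passing tests therefore show the *pipeline's* statistics are
correct and calibrated under the stated generating model — not that
real diet–microbiome effects of this size exist or would survive real
confounding.

## Numerical and design choices

* **OLS** is solved by QR (rank-checked, collinear columns named);
  SEs are classical σ̂²(XᵀX)⁻¹. Fits sharing a design are batched in
  one solve; masked cells fall back to per-feature complete-case fits.
* **Grubbs critical values** use the closed form
  G = ((n−1)/√n)·√(t²/(n−2+t²)), t the α/(2n) quantile with n−2 df.
  Zero-variance vectors mask nothing.
* **Cut labelling** renumbers clusters by first member index, so
  memberships are deterministic under relabelling.
* **Ties** in agglomeration follow scipy's deterministic ordering;
  dendrogram exports carry branch lengths as merge-height differences
  so root-to-leaf distance equals the root height.
* **Degenerate inputs**: constant exposures, fewer than
  `min_complete_cases` rows, or rank-deficient designs yield unusable
  records (with reasons) rather than exceptions; pairs pooled from
  k = 1 cohort get no Q and cannot pass the gate.
* **Determinism**: one `numpy.random.default_rng(seed)` stream per
  simulation; pipeline outputs are written with fixed float formats
  and hashed into the manifest; identical config ⇒ identical bytes.
* **Problem sizes** in the test-suite and acceptance script — a
  920-subject null study (2 400 exposure–feature pairs) and 60–100
  replicate planted-effect studies of 850 subjects — were chosen as
  the smallest sizes at which the Monte-Carlo error bands on
  calibration, coverage and sensitivity are tight enough to be
  informative.

## Known limitations

* The per-cohort model is a plain linear model on transformed
  abundances; zero-inflated, compositional (e.g. log-ratio) and
  mixed-model alternatives are out of scope by design.
* Grubbs masking operates on marginal feature values. When an effect
  is so strong that a feature's extremes are dominated by the exposure
  itself, masking trims genuine signal and attenuates estimates. At
  the default effect/noise ratio a small residual attenuation remains
  — about 0.25 pooled SE (≈1 % of the planted effect) in the
  replicate studies — which places measured 95 % CI coverage near
  93 % rather than exactly 95 %; stronger effect/noise ratios inflate
  this bias considerably (measured by ablation: disabling the Grubbs
  stage removes it).
* Energy adjustment implements the density method only; the residual
  method is intentionally not provided.
* The heterogeneity gate's Q test is low-powered at k = 4; moderate
  real heterogeneity will pass the gate. The sign-flip checks use
  strong heterogeneity precisely because that is what the gate can
  reliably reject.
* FFQ exposures are treated as error-free; attenuation from dietary
  measurement error is not modelled.
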