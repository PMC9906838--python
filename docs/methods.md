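# Methods

## Outcome and data model

The outcome throughout is breast-cancer-specific survival (BCSS): the
probability of not dying of breast cancer by a given time. Other-cause
deaths are treated as censoring, not as competing events; the package
records them distinctly (`event = other_death`) so a competing-risks
re-analysis remains possible downstream, but no cumulative-incidence
machinery is included. Follow-up is not truncated at any horizon; absolute
predictions are evaluated at exactly t = 10 years.

A cohort links a clinical table (one row per patient) to a genes × samples
expression matrix. Missing clinical values are explicit missing flags —
never zero, since zero is a valid node count. Expression is per-gene
z-scored with the sample standard deviation (n − 1 denominator), the
dominant convention in expression preprocessing; zero-variance genes are
dropped and logged, and normalisation is idempotent to 1e−8.

## Signature archetypes

Published genomic risk scores fall into three computational shapes, each a
declarative config object rather than hard-coded constants:

* **linear** — score = offset + Σ w_g · x_g, optionally clipped to scale
  bounds (recurrence-score and EndoPredict-style scores). Missing signature
  genes contribute 0, which on z-scored data imputes the cohort mean — the
  least-biased single-value imputation under this normalisation; coverage
  is always reported.
* **centroid** — per-patient Spearman correlation against class reference
  profiles combined with class weights, plus optional clinical terms (the
  risk-of-recurrence "-C" shape, also usable for an EPClin-like
  combination). Spearman is the default because the scores were designed on
  a different measurement scale; it is rank-invariant to the monotone part
  of any rescaling. Pearson is switchable per definition.
* **template** — Pearson correlation with a single reference profile
  (MammaPrint's shape); higher correlation with the good-prognosis template
  means lower risk, so its Cox hazard ratio is expected below 1.

Patients whose signature-gene profile is constant have undefined
correlations; they are flagged, never silently scored.

Surrogate binary status from one gene's expression (KI67 from *MKI67*)
uses a two-component univariate Gaussian mixture fitted by EM:
deterministic median-split initialisation, convergence at an absolute
log-likelihood change below 1e−8 (cap 500 iterations, non-convergence
returns the best iterate with a warning), variances floored at 1e−6 of the
data sd to prevent collapse. The component with the larger mean is
"positive"; a posterior of exactly 0.5 is assigned negative
(deterministic, conservative). Dichotomisation error is bounded below by
the overlap of the components: at 4 component-sd separation the optimal
rule already errs on ≈ 2.3% of points, so sub-1% accuracy is only expected
at separations of roughly 5 sd and beyond; the tests check both regimes.

## The absolute-risk engine

The clinical model is a proportional-hazards specification per ER stratum
(separate baselines because the underlying hazards differ): a prognostic
index PI = Σ βⱼ·(fⱼ(xⱼ) − cⱼ) over transformed covariates (log tumour
size, log1p nodes, grade indicators, centred age, HER2/KI67 indicators,
detection mode), treatment log-hazard-ratios, and a tabulated baseline
survivor function S₀(t) on [0, 15] years. A reference patient has PI = 0.
Missing optional covariates (KI67, grade, PR) fall back to the reference
level with a logged flag. KI67 appears only in the ER-positive default
config.

Between knots S₀ is interpolated linearly on the complementary log-log
scale, which preserves proportional-hazards structure between tabulated
points; on segments where S₀ is still 1 the cumulative hazard is
interpolated linearly instead. No extrapolation beyond the table — a
request past the last knot is an error, not a guess.

Absolute survival is S(t) = S₀(t)^exp(PI + treatment terms). The
chemotherapy benefit is S(10) with minus without the second-generation
chemotherapy log-HR, holding the patient's other recorded treatments
fixed, in percentage points. A rescaled genomic term enters both arms.

The shipped coefficient files are illustrative transcription-style values,
clearly editable; the engine is exact-testable against hand-computable toy
specifications, which is what the unit tests do.

## Offset Cox fitting and rescaling

To validate the clinical model externally rather than re-fit it, PI enters
the partial likelihood as an offset with coefficient fixed at 1; only the
signature coefficient β is free. Ties are handled by the Efron
approximation (the default of mainstream survival software).
Newton–Raphson with step-halving on a likelihood decrease converges at a
coefficient change below 1e−9 (cap 100 iterations; failure raises with the
iteration trace). Standard errors come from the observed information; CIs
are exponentiated Wald intervals. Nested models are compared by the
likelihood-ratio statistic 2·(ll_full − ll_restricted) against χ²(df) — the
analysis-of-deviance reading of an "ANOVA" on nested Cox fits. An optional
ridge penalty exists for deliberately ill-posed fits (many noise
covariates); it is off by default.

The fitted term is rescaled by c = log(mean exp(β·g)), computed via
log-sum-exp so extreme products cannot overflow. After rescaling the
empirical mean hazard ratio of the added term is 1 to 1e−10 and the
ordering of patients' hazards is unchanged, so the host baseline remains
valid.

## Evaluation

* **Calibration**: cohort-mean predicted 10-year BCSS (percent) minus the
  Kaplan–Meier estimate at 10 years (lifelines' product-limit estimator
  behind the module surface). Negative = underestimation.
* **Discrimination**: Harrell's c over usable pairs — the earlier time must
  be an event (ties in time with exactly one event are usable; ties in risk
  score 1/2). The CI uses the linearised (infinitesimal-jackknife) variance
  of the ratio-of-U-statistics estimator: Var ≈ Σᵢ (aᵢ − c·bᵢ)² / M², with
  aᵢ, bᵢ the per-subject score and pair counts and M the total usable
  pairs.
* **Optimism**: out-of-bag bootstrap — refit on each of B resamples,
  compare apparent c with c on the out-of-bag complement; optimism is the
  mean difference. A prespecified (non-fitted) score concentrates at 0; a
  deliberately overfit model is positive. The classic
  apparent-minus-original variant is implemented as an alternative. One
  master seed spawns per-replicate substreams, recorded for exact reruns.
  Calibration-difference optimism is reported as the optimism of the
  difference (the quantity itself is an interpretation; it is flagged as
  such in the report schema).
* **Reclassification**: chemotherapy-benefit categories low < 3, 3 ≤
  intermediate ≤ 5, high > 5 percentage points — both boundary values
  belong to the intermediate band, the only reading that partitions the
  line given strict outer inequalities. Tables are 3×3 counts with movement
  summaries; percent reclassified is rounded half-away-from-zero for
  display while the exact fraction is kept in JSON. ER-negative patients
  are excluded from benefit reclassification by default (flag to include).

## Synthetic cohorts

The generator emulates a large linked clinical/expression cohort. Clinical
marginals default to: 76% ER-positive, 53% PR-positive, 12% HER2-positive,
47% node-positive, grade proportions 9/39/48 (renormalised), median age
61.8 y (sd 12, truncated to 21.9–96.3), median tumour size 23 mm
(log-normal, σ = 0.6, clipped to 1–403 mm), chemotherapy 79/20/1%
none/second/third generation, 61% hormone therapy (given preferentially to
ER-positive patients so the joint distribution is sensible), 59%
radiotherapy. Detection mode defaults to "unknown" for everyone — the
screening flag was unavailable in the population being emulated — with
configurable probabilities for exercising detection terms.

Dependence is induced by a single latent "aggressiveness" factor through a
Gaussian copula: marginals are preserved exactly in distribution while
grade, size, nodes, chemotherapy, KI67 and (negatively) ER status co-vary.
The signature-gene block loads on the same factor with alternating sign
(half positive, half negative), so weighted-sum, centroid-correlation and
template-correlation scorers all carry signal; *MKI67* is bimodal around
a latent KI67-high state. Expression is z-scored on output.

Survival truth: exponential baseline by default (closed-form inversion;
Weibull optional) with hazard multiplier exp(PI_true + treatment terms +
β_true·g), β_true = 0.5 by default; independent other-cause mortality and
independent random censoring plus an administrative cut-off at 29 years.
Baseline rates (0.010/yr ER-positive, 0.030 ER-negative), other-cause rate
0.013 and censoring rate 0.035 were chosen so a default cohort lands near
median follow-up 9.5 years with roughly a third of patients dying of
breast cancer — targets of the emulation, not assertions. A second entry
point, `simulate_from_predict_spec`, draws event times by inverting a risk
specification's own baseline at each patient's hazard multiplier, making
that model perfectly calibrated by construction; the self-calibration
check uses it at n = 20,000 and requires agreement within 1 percentage
point.

What the generator does **not** emulate: real gene–gene covariance beyond
the one-factor block, copy-number structure, platform effects, cohort-era
treatment drift, or informative censoring. Passing tests therefore
demonstrate the correctness of the machinery under a proportional-hazards
world, not the clinical performance of any commercial assay.

## Numerical and design notes

* The partial likelihood is location-invariant in the linear predictor;
  the implementation shifts by the maximum before exponentiating, so large
  offsets cannot overflow.
* Scoring problem sizes in the test-suite simulations (n = 2,000 × 200
  replicates for CI coverage; n = 5,000 × 100 for closure bias; n = 20,000
  for self-calibration; n = 50,000 for marginals) were chosen as the
  smallest at which the corresponding law-of-large-numbers or coverage
  statements are sharp.
* Recovery and null-coverage simulations fit within a single ER stratum,
  because the generating baseline differs by stratum and the analysis
  model is always stratified.
* Published hazard-ratio tables for commercial signatures cannot be
  reproduced without the proprietary constant sets and the original
  patient-level cohort; the package therefore validates its estimator
  against brute-force oracles and simulation truth instead, and treats the
  printed reclassification matrices and calibration pairs — which are
  complete summaries — as exact desk-scale inputs.

## Known limitations

* No competing-risks estimands; BCSS only.
* Single-signature models only (no joint multi-GRS fits), matching how
  such scores are used clinically.
* The c-index CI is asymptotic; at very small n it can touch the [0, 1]
  clip.
* The EM dichotomiser assumes exactly two Gaussian components; heavy tails
  or three-mode markers will be forced into two groups.
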