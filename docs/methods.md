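# Methods

This note records the models, estimators, and design choices behind
`dkdrisk`, and what the synthetic-data experiments do and do not establish
about behaviour on real cohorts.

## Study design being emulated

A retrospective type-2-diabetes cohort is screened at an index date
(age ≥ 18, baseline UACR < 30 mg/g, baseline eGFR ≥ 30 mL/min/1.73 m², no
prior renal failure, at least one follow-up UACR or eGFR measurement), split
2:1 into a validation and a test set, and followed ~7 years for three renal
outcomes defined from longitudinal labs. Published risk equations predict
each patient's 7-year absolute risk; the validation split measures
discrimination (AUROC) and calibration (decile slope/intercept, GND test);
outcomes with GND p < 0.05 are recalibrated on the validation split by a
log-log baseline-hazard multiplier, which is then frozen and re-evaluated on
the test split. Diabetes duration is set to 5 years for every patient
(typical EHR cohorts lack onset dates).

## Outcome ascertainment

An outcome fires on a *run* of consecutive qualifying measurements of the
defining analyte — microalbuminuria: UACR ∈ [30, 300); macroalbuminuria:
UACR ≥ 300; renal failure: eGFR < 15, with eGFR derived from serum
creatinine by the 4-variable MDRD equation — containing at least
`confirmations` (default 2) measurements and spanning at least
`min_gap_days` (default 90) from first to last. An intervening sub-threshold
value resets the run. For sparse labs this is exactly "two consecutive
measurements ≥ 90 days apart"; for dense labs the confirmatory measurement
90+ days later simply has further qualifying values in between. The strict
"adjacent pair ≥ 90 days apart" variant was rejected because it can never
fire when the sampling interval is shorter than the gap, so detection would
not converge to the latent truth as visit density grows. The event date is
the first measurement of the qualifying run (onset convention); otherwise
the patient is censored at their last measurement of that analyte, so each
outcome carries its own person-years. Macroalbuminuria is ascertained
independently of microalbuminuria status, and patients are simultaneously
at risk for all three outcomes.

Consequence of lab-based ascertainment: with visit interval v, an event at
latent time T is recorded near T + U(0, v) and needs a confirming visit
≥ 90 days later before the series ends, so observed risks are those of a
slightly shortened effective horizon. On the complementary log-log scale
this is close to a constant offset and is absorbed by the recalibration
multiplier — which is why a zero-miscalibration world still yields a small
negative fitted δ (bounded by roughly ln(1 − (v + 90 d)/horizon)).

## Risk equations

Four families share the proportional-hazards form risk(t) = 1 −
exp(−H₀(t)e^LP): Cox with reported baseline survival (H₀ = −ln S₀(t)),
exponential (λt), Weibull (λt^ρ), and Gompertz ((λ/φ)(e^{φt} − 1)); the
Gompertz form covers annual-cycle equations evaluated directly as a t-year
cumulative risk rather than by cycle simulation, since only the t-year
probability is consumed downstream. Equations are loaded from YAML/JSON
registries (name, family, horizon, baseline parameters, coefficient and
centering maps); coefficient names must resolve against the baseline schema
or be backed by registry-declared constants (e.g., ethnicity indicators not
collected in the target cohort). The registries shipped under
`src/dkdrisk/data/equations/` carry *illustrative placeholder* coefficients
in the published structural forms; users supply real published values.
Predictions over multiply-imputed tables are pooled by the element-wise
arithmetic mean.

## Validation metrics

* **AUROC** is the exact Mann–Whitney rank statistic with tie correction.
  The event flag is "event ascertained at any time during follow-up";
  early-censored patients count as non-events. This matches the crude
  event-risk convention but is a known limitation — no censoring-weighted
  time-dependent AUROC is attempted.
* **Kaplan–Meier / Greenwood** is a direct product-limit computation (events
  precede censorings at ties; follow-up beyond the horizon is
  administratively censored there). With no censoring before the horizon it
  reduces exactly to events/n with binomial variance. `lifelines` serves as
  an independent oracle in the test suite, not as the implementation,
  because the GND test needs the raw Greenwood variance at the horizon.
* **Decile calibration** splits the cohort into 10 predicted-risk groups
  (stable sort, ties broken by patient id; group sizes differ by ≤ 1) and
  fits an unweighted OLS line through the (mean predicted, observed) points.
  Observed risk is KM by default; a crude-proportion variant is available.
* **GND test.** X² = Σ (O_g − P_g)²/Var_g over usable groups; groups with
  fewer than 5 events are merged into the adjacent lower decile (the first
  group merges forward). Merged observed risks are patient-count-weighted
  means and variances n²-weighted — exact without censoring, an
  approximation under it. **Degrees of freedom equal the number of usable
  groups**, not groups − 1: the predictions under test are fully
  prespecified (external validation), so the group residuals are
  independent and the null statistic's mean is the group count — verified
  by simulation (using G − 1 roughly doubles the type-I error). Even so,
  the observed-variance (Wald) denominator leaves a residual type-I
  inflation of 1–3 percentage points when per-group event counts are low;
  this is a property of the statistic itself.

## Recalibration

`apply_delta` implements risk′ = 1 − (1 − risk)^{e^δ} via
expm1/log1p for numerical accuracy; risk = 0 passes through, risk = 1 is
clamped to 1 − 10⁻¹² with a warning (log-log domain). The default estimator
is closed-form cumulative-hazard moment matching,
δ̂ = ln(−ln(1 − O)) − ln(mean −ln(1 − pᵢ)) with O the KM (default) or crude
observed risk, which makes the mean recalibrated cumulative hazard equal
−ln(1 − O) exactly. It is exactly consistent under homogeneous per-patient
hazards; under heterogeneity it carries a small Jensen bias of order
−Var(H)/(2·mean H) on the log scale. An intercept-only complementary
log-log maximum-likelihood variant (`method="mle"`, censoring ignored) is
provided for comparison; because it targets the crude rather than the
KM-consistent risk it should not be mixed with KM-based evaluation.
Stratified mode fits δ independently within user-supplied predicted-risk
strata (upper bounds covering (0, 1]); application routes each patient by
their *original* predicted risk, and the step discontinuity this creates at
a stratum boundary is preserved, not smoothed. A helper proposes a boundary
at the first sign change of the decile residuals. One stratum reproduces
global mode bit for bit.

## Synthetic cohort generator

The generator's defaults are the study conditions: 3,986 patients whose
baseline marginals match the published cohort description (continuous
variables as independent truncated normals with the location solved so the
*truncated* mean equals the published mean; binary/categorical variables by
prevalence), 7-year follow-up, quarterly labs, exponential per-outcome
censoring at 0.02/yr, and exponential proportional-hazards latent event
times with baseline yearly hazards solved from the published crude risks
(−ln(1 − risk)/7: 0.0630, 0.0088, 0.0013 for micro-/macroalbuminuria/renal
failure) plus mild covariate effects (HbA1c, SBP, baseline UACR, eGFR)
centered at the cohort means. The published overall triglyceride SD is
printed with a corrupted leading digit; 101.92 is used, consistent with the
subgroup values. Baseline eGFR is drawn as its own marginal rather than
derived from creatinine, because the published creatinine and eGFR means
are not MDRD-consistent and marginal fidelity is the contract; follow-up
creatinine values are back-calculated from intended eGFR via MDRD, so the
ingest pipeline exercises the conversion. Post-event lab values persistently
sit on the qualifying side of the threshold with 10% relative jitter and
pre-event values below it, so the ascertainment rule is the only event
detector. An injected log-multiplier `true_delta` scales every simulated
cumulative hazard but is withheld from the matching prediction equation —
ground truth for recovery experiments.

What the generator does **not** emulate: between-variable correlations
(hook available, default off; none are published), visit-schedule
irregularity, informative censoring, calendar time, coding-based
comorbidity ascertainment, and assay noise that crosses outcome thresholds
before the latent event. Passing tests therefore establish the estimators'
correctness under a clean proportional-hazards world, not robustness to
real-EHR messiness.

## Imputation

Missing baseline cells (MCAR injection in the synthetic world) are filled by
fully conditional specification: per column, an OLS model on all other
variables with predictive mean matching (5 nearest donors, fills are always
observed values) for continuous targets, and a multinomial-logistic draw for
categorical targets, 10 cycles, 5 chains by default, seeded and
deterministic. This stands in for discriminant-function FCS; point
predictions are pooled by averaging and no Rubin's-rules variance pooling is
done, since only pooled risks feed the downstream metrics.

## Numerical and orchestration choices

All randomness flows from one root seed through spawned per-stage seeds;
reports are written with sorted keys and no timestamps, so a rerun is
byte-identical. The 2:1 split assigns floor(2n/3) shuffled patients to
validation (3,986 → 2,657/1,329; the published 2,659/1,327 is one possible
realization of a different rounding, reproduced only as fixture numbers).
Recalibration parameters are fitted on the validation split only and frozen
before test-split evaluation; the test suite audits this by refitting from
the split ids. Stratum routing uses half-open intervals: a risk exactly at
a boundary belongs to the upper stratum (e.g., "< 2.4%" vs "≥ 2.4%").

Simulation sizes used by the test suite and acceptance script: marginal
fidelity at n = 4,000; δ-recovery at n = 5,000 with 100–200 replicates on a
homogeneous hazard calibrated to the published microalbuminuria risk (the
regime where the moment estimator is exactly consistent); GND type-I error
at n = 2,000 over 200–500 replicates with risks Uniform(0.2, 0.6) (moderate,
microalbuminuria-like levels — very low per-group event counts inflate any
observed-variance chi-square); end-to-end runs at the full study size
n = 3,986 with the published microalbuminuria multiplier 1.212 as the
injected miscalibration.

## Known limitations

* Post-recalibration test-split calibration is not pure type-I error: the
  validation-fitted δ̂ carries sampling noise that is shared across every
  test decile, adding a noncentrality of roughly n_test/n_val to the GND
  statistic for any 2:1 design, independent of cohort size. Together with
  the Wald inflation above, the test-split GND rejects a recalibrated
  outcome in roughly 10–15% of replicates even when the recalibration
  family is exactly correct. This is intrinsic to split-sample
  recalibration, not a defect of the estimator.
* The moment estimator's heterogeneity bias and the ascertainment detection
  lag both shift δ̂ away from the generating multiplier; both are shared
  between splits and thus calibration-neutral, but recovered δ̂ values
  should not be read as unbiased estimates of a latent-world multiplier
  when labs are sparse.
* Renal-failure events are rare (~0.9% over 7 years); stratified
  recalibration and decile diagnostics for that outcome need cohorts far
  larger than the study size to be stable, which is why the shipped
  experiments focus on microalbuminuria.
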