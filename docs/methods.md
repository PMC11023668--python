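# Methods

## The longitudinal phenotype model

All simulation and theory in `ehrpgx` rest on one generative model for a
biomarker level at time *t*:

    Y_t = intercept + β₀·G + β_E·E + γ_E·G·E + D_t·(β_D + γ_D·G) + ε_t

* `G` — allele dosage of a panel variant, drawn binomial(2, MAF)
  (Hardy–Weinberg); a many-small-effect polygenic background can be added,
  in which case the standardized true score contributes
  `sqrt(var_baseline)` per SD to the linear predictor.
* `E` — a *persistent* per-person environment draw, N(0, var_env_persistent),
  shared by every measure of that person.
* `ε_t` — i.i.d. occasion noise, N(0, var_env_occasion), independent across
  measures.
* `D_t` — the drug indicator, switching from 0 to 1 on the day of the first
  primary-medication prescription with no pharmacodynamic ramp. Since
  post-treatment windows start six months after initiation, a steady-state
  effect is a safe simplification.
* `scale="log"` applies the same linear predictor to `log Y`, so the drug
  acts multiplicatively on the biomarker (needed for the PRS analyses on an
  LDL-like trait).

The persistent + occasion split of the environment is this package's own
choice: it is the minimal structure under which the baseline variance
decomposes into the shared (`v_pers`) and transient (`v_occ`) components
that the bias theory requires. Real biomarkers have autocorrelated
environments between these extremes; nothing downstream depends on the
split beyond those two variances. The gene–environment interaction γ_E
acts through the first panel variant and defaults to 0; because `E` is
persistent, it cancels in differences either way.

## Baseline-adjustment bias: closed form

Writing one person's two measures as `Y0 = β₀G + P + e0` and
`Y1 = β₀G + P + β_D + γ_D·G + e1` with `Var(P) = v_pers`,
`Var(e) = v_occ`, `Var(G) = v_g = 2·maf·(1−maf)`, the difference
`ΔY = β_D + γ_D·G + e1 − e0` is free of β₀, so the unadjusted regression
of ΔY on G has expectation γ_D exactly.

Jointly regressing ΔY on (G, Y0) — "baseline adjustment" — solves 2×2
normal equations with determinant `v_g(v_pers + v_occ)` (hence an error
when the baseline has no non-genetic variance) and dosage coefficient

    E[b_adj] = γ_D + β₀ · v_occ / (v_pers + v_occ).

The coefficient's bias is first-order in β₀; the *association statistic*
(squared standardized effect per observation, `a²·Var(G|Y0)/Var(resid)`,
proportional to the non-centrality of the test) scales as β₀² near β₀ = 0
when γ_D = 0. Both quantities are computed so the quadratic-bias claim can
be checked on whichever scale is meant; the package verifies the exponent
by fitting a power law to the simulated statistic over |β₀| ∈ [0.15, 0.4]
and recovering 2 within ±0.2. Baseline adjustment is implemented as the
joint regression (standard GWAS practice) rather than two-stage
residualization; the two differ only in standard errors, not in the
coefficient.

In the PRS sign-reversal demonstration the drug acts multiplicatively, and
the same algebra applied to the linearized natural-scale model gives
`treated adjusted ≈ exp(β_D) · control adjusted`: both adjusted
coefficients are spuriously positive, with the treated one attenuated by
the multiplicative drug factor. The tests assert this model-implied
relation rather than exact equality of the two coefficients.

## Cohort emulation

Dates are integer days from an arbitrary epoch. Windows are half-open
`[a, b)` except the baseline window, which is inclusive at both ends:
baseline `[start − lookback, start + 7]` with a 90-day (stringent) or
365-day (lenient) lookback; post-treatment `[start + 183, start + post_max)`
with `post_max` 548 (stringent) or 730 (lenient) days. Within a window the
`single` mode takes the measure closest to treatment start (ties resolved
to the earlier, pre-treatment measure; the earliest measure for the post
window) and the `average` mode the mean value with its mean date.

The QC cascade runs in a fixed order — co-medication rules; (i) baseline
and post measures available; (ii) a primary-care record other than
baseline/primary medication at least two years (730 days) before start;
(iii) a broad-class prescription after the post measure; (iv) drug change
between start and post measure; (v) prescription regularity; (vi) minimum
baseline level (default: LDL-C ≥ 2 mmol/L, others configurable); drug-group
size ≥ 20; cohort size ≥ 500 (warning only) — and counts each excluded
person at the first failing stage, so `n_input = survivors + Σ removals`
holds exactly.

Decisions where the procedure was genuinely open:

* **Regularity discretization.** "A prescription every two months" is
  implemented as 61-day windows over `[start, post_date)`; a trailing
  partial window counts if at least half a window long (≥ 30.5 days → the
  31st day). The cutoff defaults to 0.8 and is configurable, since only
  observed regularities (88% / 42% in the two source populations), not the
  cutoff, are published; `regularity_mode="min_one"` reproduces the relaxed
  rule of requiring a single prescription between start and post measure.
* **Drug change (iv).** Stringent excludes both type and dose changes;
  lenient excludes type changes only, keeping the start dose as a
  covariate. This is the most natural reading of scenarios differing in
  "handling of treatment changes".
* **Prior record (ii).** Any measure (any biomarker) or non-primary
  prescription dated ≤ start − 730 days qualifies.
* **Combination products** (primary medication co-formulated with another
  same-class agent) always exclude. Same-class other drugs within ±365 days
  of start exclude, unless in lenient mode they are a configured add-on
  present both before and after start, in which case they become a
  covariate flag. Persons whose only primary-medication items are
  combination products never become candidates (they have no primary
  prescription to define a start).
* **Dose** is parsed from the free-text description
  (`<number>[ ]mg`, case-insensitive, first match) and missing doses are
  imputed with the per-drug-type median; a drug type with no observed dose
  leaves the person in the cohort but out of the dose covariate.

Drug-naive controls use the first available pair of measures spaced
183–1095 days apart — the minimum and maximum allowed interval between
baseline and post-treatment measures.

## Phenotypes and covariates

Responses are `post − baseline` (absolute) or `log(post) − log(baseline)`
(log-relative; rows with non-positive values are dropped from that mode
with a reason). Covariate adjustment residualizes on sex, age at start,
time from start to post measure, drug-type indicators, dose, add-on flags
and k generated confounder components (default 4) standing in for genotype
principal components — no population structure is simulated. The response
is never adjusted for baseline. The rank-based inverse normal transform
uses the Blom offset, `Φ⁻¹((r − 3/8)/(n + 1/4))`, with ties receiving mean
ranks; the offset is configurable since conventions differ. HbA1c converts
between IFCC and NGSP units by the master equation
`NGSP% = 0.09148 × IFCC + 2.152`.

## Association

Per-variant effects come from ordinary least-squares of the
(covariate-adjusted) response on allele dosage, with t-distribution
p-values; monomorphic dosages are flagged, not fitted. Plain per-variant
regression deliberately replaces whole-genome mixed-model machinery: the
synthetic panel is generated independent and unstructured, so the estimand
coincides and LD clumping is unnecessary. The `DrugResponseGWAS` /
`DrugResponseGWASResults` pair exposes the scan statsmodels-style.

## What the generator does and does not emulate

Emulated: additive genetic and polygenic baseline effects, persistent and
occasion environment, additive or multiplicative drug action with optional
pharmacogenetic modulation (per-variant or PRS-linked), irregular
Poisson-process visit schedules, prescription refill streams with
configurable regularity, same-class co-medication, combination products,
add-on therapy and drug switches, sex/age nuisance effects.

Not emulated: disease-progression dynamics, pharmacokinetic ramps,
informative visit processes (visits independent of biomarker levels),
population structure and relatedness, cross-class polypharmacy, real
prescription vocabularies (a toy code map stands in). Passing tests
therefore validate the pipeline's logic and the bias theory under the
stated model, not robustness to these real-data features. One deliberate
artefact is retained: measures falling in the inclusive
`(start, start + 7]` baseline tail carry the drug effect in the generator,
mirroring the mild contamination the same window rule produces on real
data.

## Problem sizes and numerical choices

The packaged scenarios run at n = 800–4,000 simulated persons (cohorts of
roughly half that size after QC), large enough that the two causal variants
of the `statin_like` scenario are recovered at the 0.05/20 family-wise
threshold with high margin. The estimand-recovery and bias grids use
direct two-timepoint simulation at n = 20,000 per replicate (200 replicates
per grid point for estimand recovery; 10 × 100,000 draws per point for the
bias oracle; 40 replicates per point for the power-law fit), chosen so
Monte-Carlo standard errors are small against the effects being measured.
Tolerances follow the 3-standard-error convention throughout. One master
seed drives every stage through independently derived substreams, so any
stage can be rerun in isolation; identical configuration and seed give
byte-identical outputs.

## Known limitations

The closed-form bias assumes exactly two timepoints and homoskedastic
occasion noise; averaged multi-measure windows shrink `v_occ` by the number
of measures averaged, which the theory parameters must reflect if applied
to averaged phenotypes. The monotonicity guarantee (stringent survivors ⊆
lenient survivors) is established for single-measure selection; with
averaged measures the two scenarios may select different post dates and
regularity denominators. Real-vocabulary support, cross-class polypharmacy
and event (rather than biomarker) outcomes are out of scope.
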