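# Methods

## Study design being implemented

The package operationalizes a preference-based instrumental-variable (IV)
evaluation of initial visit modality in a specialty clinic. The cohort is
every patient's first qualifying new patient visit (NPV) inside a study
window, restricted to ten common cardiology diagnosis groups. The outcome
is the count of follow-up visits with any clinician in the log within six
months of the index NPV. The treatment is a binary telemedicine indicator
(video or phone vs in person). The instrument is the treating clinician's
telemedicine fraction of qualifying NPVs over the study window — a proxy
for how much telemedicine that clinician keeps on their new-patient
schedule. Identification rests on pseudorandom assignment of referrals to
the clinician with the next open slot; the two falsification tests probe
the exclusion restriction and independence assumptions empirically.

## Synthetic data-generating process

The generator (`teleiv.simulate`) emulates the statistical structure the
analysis assumes, with every causal quantity held in a sidecar
(`SimulationTruth`) that never enters the emitted visit log.

* **Clinicians.** `n_clinicians` (default 40) receive telemedicine
  propensities $\pi_j$ drawn from a bathtub-shaped Beta(0.60, 0.52)
  (mean ≈ 0.536), so realized propensities span essentially 0–1, matching
  a practice whose clinicians range from never to always using telemedicine
  for new patients.
* **Patients.** One index NPV per synthetic patient;
  `npv_per_clinician_mean` (default 138.2, i.e. ~5,500 NPVs) patients are
  assigned to clinicians uniformly at random. With
  `sorting_violation` $\rho \ne 0$ assignment is tilted: weights
  $\propto \exp(-\rho\, U_i\, z(\pi_j))$ send higher-severity patients to
  low-telemedicine clinicians.
* **Severity.** A latent $U_i \sim N(0,1)$ drives both modality and
  outcome. `severity_covariate_load` $\lambda$ makes age correlate with
  $U$ (corr = $\lambda$, default 0), which is what lets severity leave a
  trace in *observed* covariates when a detectable sorting violation is
  wanted.
* **Treatment.** $T_i \sim \text{Bernoulli}(\text{logit}^{-1}(
  \text{logit}(\pi_j) + \gamma U_i + x_i'\kappa))$ with small centered
  covariate terms $\kappa$ (age −0.25 per SD, private insurance +0.30) so
  the patient mix differs by modality without moving the overall share.
  `confound_treat` $\gamma$ defaults to 0.5.
* **Outcome.** Location $\mu_i = \alpha_d + \beta_d T_i + x_i'\theta +
  \delta U_i + c\,(1-\pi_j)$, where $c$ is `exclusion_violation`
  (default 0; setting it makes low-telemedicine clinicians schedule extra
  follow-ups in *both* periods, the violation the exclusion test must
  detect). `confound_outcome` $\delta$ defaults to 0.5. Two outcome
  families:
  * `truncated_poisson` (default): counts $\sim$ Poisson(max(0.01, $\mu$)) —
    realistic nonnegative integers; the floor makes the linear estimand only
    approximately $\beta_d$;
  * `gaussian_linear`: real outcome $\mu + N(0, \sigma_y^2)$
    ($\sigma_y$ = `outcome_sd`, default 0.75), floored at zero and
    *stochastically rounded* to an integer row count. Stochastic rounding
    preserves the conditional mean exactly wherever the real outcome is
    nonnegative, so exact linear parameter recovery holds when negative
    outcomes are rare. The `recovery_config()` preset therefore raises all
    baselines to $\alpha_d = 4.0$ (P(negative) < 0.1% even with
    unit-strength confounding) — the parameter region used for recovery and
    coverage studies.
* **Follow-ups** are emitted as dated return-visit rows at uniform offsets
  of 1–183 days; each is telemedicine with probability `sticky_prob_tele`
  (0.836) after a telemedicine NPV and `sticky_prob_inperson` (0.444)
  after an in-person one, an independent coin per visit. Telemedicine
  visits are video with probability 0.951, else phone.
* **Prepandemic log**: same clinicians and outcome structure with
  treatment fixed at 0 and all rows in person — the placebo period the
  diagnostics need.

Defaults for the diagnosis mix (ten groups, dyslipidemia largest at 21.5%,
preoperative evaluation smallest at 1.9%), covariate marginals (54.2%
female, 44.9% private insurance, 86.3% English-preferring, age
$N(56, 17.5^2)$ clipped to [18, 95], distance lognormal with median 17.8
miles), and effect sizes (chest pain +0.369, dyspnea +0.370, palpitations
+0.349, syncope/dizziness +0.298, coronary artery disease −0.295,
dyslipidemia −0.245 follow-ups per patient; zero for the other four
groups) reproduce the marginal structure of the emulated practice.
Baselines $\alpha_d$ are only partially pinned down by that structure
(overall ≈ 0.57 follow-ups/patient, heart failure highest ≈ 1.05,
preoperative lowest ≈ 0.26); the remaining groups are interpolated to
plausible values preserving the overall mean. The fellow-present marginal
(0.30) and the covariate outcome effects $\theta$ (order 0.02–0.05) are
deliberately arbitrary small values, documented as such. Identical config
and seed give byte-identical tables (all randomness flows through
`numpy.random.Generator` seeded from `seed` with a fixed stream tag per
period).

### What the generator does *not* emulate

Referral queues, appointment calendars, within-patient repeat NPVs,
serial correlation of a patient's follow-up decisions (stickiness is an
independent coin), measured severity, seasonality, or clinician drift over
time. Passing tests therefore show the *estimators and procedures* behave
correctly under the assumed structure — not that the assumptions hold in
any particular real practice.

## Cohort rules

* Six months = **183 days**, the half-open interval (0, 183] after the
  index date; same-day visits are excluded. (The printed convention "6
  months" does not fix a day count; 183 ≈ 366/2.)
* First qualifying NPV per patient is the index; date ties break by
  clinician id.
* Follow-ups count visits with *any* clinician in the log (all rows are
  in-specialty by construction).
* The instrument includes the patient's own visit in the clinician's
  fraction; `loo_instrument=True` switches to the leave-one-out variant,
  offered because the mechanical own-observation term is a known
  small-sample IV concern.
* Eligibility: ≥ 10 qualifying NPVs and absence from an explicit exclusion
  list.
* Age bands [0,45), [45,65), [65,∞); `log_distance = ln(max(d, 0.1))`
  miles; period boundary 2022-01-01 (index dates on/after it are the
  "2022–23" period); missing covariates are handled complete-case with
  per-field logged counts.

## Estimators

OLS and 2SLS are implemented directly on dense linear algebra (QR rank
check with pivoting, least-squares solve). Design matrices one-hot encode
categoricals against fixed reference levels (age <45, race White, language
English, insurance Private, interpreter No, fellow No, earliest year);
treatment-effect estimates are invariant to the reference choice, which is
asserted in tests. Sex is excluded from the default adjustment set (a flag
restores it); year enters as categorical fixed effects.

2SLS is genuinely two-stage: stage 1 regresses each endogenous column on
[instruments, covariates]; stage 2 regresses the outcome on [fitted
endogenous, covariates]. The robust covariance is the **HC1** sandwich
$(\hat X'\hat X)^{-1}(\sum_i \hat x_i \hat x_i' \hat e_i^2)(\hat X'\hat X)^{-1}\cdot n/(n-k)$
with *structural* residuals (actual treatment). The first-stage F is the
robust Wald statistic on the instrument coefficients (minimum across
endogenous columns when there are two). A cluster-robust (CR1, by
clinician) variant exists behind a flag but is off by default — the
design's stated inference is heteroskedasticity-robust, not clustered.
CIs use the normal critical value 1.959964. Degenerate inputs raise typed
errors: rank-deficient designs name the collinear columns; instruments
constant after partialling out covariates raise a weak-instrument error;
zero-variance outcomes (e.g. the binary sensitivity when every patient has
a follow-up) raise a degenerate-outcome error. Strata too small for their
design, or perfectly collinear in rare covariate levels, are skipped with
a logged warning rather than aborting the battery.

The period-interaction sensitivity treats $T$ and $T \times$ late-period
as two endogenous regressors instrumented by $Z$ and $Z \times$
late-period (the period main effect is absorbed by the year fixed
effects); the reported contrast is the between-period difference in the
treatment effect.

## Falsification diagnostics

Both tests regress clinician-diagnosis **cell** summaries on the
study-period telemedicine fraction with diagnosis fixed effects, HC1 SEs,
normal p-values, cells unweighted (a `weight_by_n` flag offers
size-weighting), restricted to clinicians with ≥ 10 NPVs in *both*
periods. The exclusion test uses prepandemic mean follow-up counts as a
placebo outcome. The independence test first fits a prepandemic
main-effects-only prediction model (covariates + diagnosis, no year),
scores every study record — study-period covariate levels unseen
prepandemic collapse to the reference with a logged count — and regresses
clinician-panel mean predictions on the fraction. By construction this
detects only sorting transmitted through observed covariates; purely
latent sorting is invisible to it, which the test suite asserts directly.

## Replication-study sizes

The test suite's replication studies use scaled synthetic sizes chosen as
standard Monte Carlo practice: parameter recovery at 300 replicates of
~4,000 patients (40 clinicians × 100 NPVs, `recovery_config`); diagnostic
null calibration at 400 replicates and power at 200 replicates of 40
clinicians × 30 NPVs per period; null-effect coverage (pooled and
period-interaction) at 200 replicates of ~2,000 patients. The injected
violations are +0.5 extra follow-ups per unit of (1 − propensity) for the
exclusion test, and sorting strength 1.0 with severity-age load 1.0 for
the independence test — magnitudes fixed once when the studies were
designed. The acceptance script's recovery study uses 100 replicates.

## Known limitations

* The pooled 2SLS estimand under heterogeneous per-diagnosis effects is an
  instrument-weighted average, not the simple mean of $\beta_d$; tests
  compare pooled estimates only against zero-effect generators.
* Under the default truncated-Poisson family the linear IV estimand is
  attenuated relative to $\beta_d$ wherever the location floor binds;
  exact recovery claims are made only for the gaussian-linear family in
  the truncation-rare regime.
* The independence diagnostic inherits the procedure's own blind spot
  (latent sorting) and ignores the sampling noise of the stage-A
  prediction model, which can make it mildly anticonservative in small
  panels.
* No count-model IV (Poisson IV / control function) and no
  multiple-testing adjustment across strata: the implemented design is
  strictly linear 2SLS with per-stratum inference.
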