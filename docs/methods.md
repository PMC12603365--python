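# Methods

This note documents the statistical machinery in `strokemap`: the outcome
rules, the models, the synthetic-cohort generator that the tests exercise,
and the numerical choices made where the design was genuinely open.

## Study design being modelled

The package implements a registry-style analysis of elderly (≥65 y) acute
ischaemic stroke patients in which sarcopenia is operationalized as **low
temporal muscle thickness (TMT)**: the mean of the left and right
temporalis thickness measured on axial brain MRI, dichotomized at the
cohort 25th percentile. The analysis asks whether low TMT associates with
dysphagia, early neurological deterioration (END), period-specific
recovery, and poor functional outcome (mRS ≥ 3 / ≥ 4 at 3 months and
1 year); whether those intermediates *mediate* the TMT→outcome effect;
and whether presenting symptoms or infarct locations *modify* it.

## Outcome derivation rules

* **Dysphagia** — Functional Oral Intake Scale (FOIS) 1–6; FOIS 7
  (unrestricted intake) is non-dysphagic.
* **END** — within 21 days of onset, any of: total NIHSS increment ≥ 2;
  consciousness subscore (items 1a–1c) increment ≥ 1; motor subscore
  (items 5a–6b) increment ≥ 1; or a clinician-recorded new deficit.
  **END₄** is the stricter total increment ≥ 4. Increments are measured
  against the **running minimum** of all preceding exams (equivalent to a
  maximum over ordered exam pairs), because deterioration after early
  improvement is still a deterioration event; an admission-only reference
  is available via `reference="admission"`. The source protocol does not
  state the reference exam; the running-minimum default is our reading of
  "any neurological worsening", and both conventions are exposed.
* **Recovery** — three periods with explicit eligibility:
  in-hospital = NIHSS improvement ≥ 4 points *or* ≥ 40% from admission to
  discharge (admission NIHSS 0 ineligible; the ≥40% comparison is done
  with exact rational arithmetic on the integer scores, avoiding any
  floating-point boundary artifact at improvements like 2/5);
  post-discharge = 3-month mRS strictly below discharge mRS (discharge
  mRS 0 or 6 ineligible); chronic = 1-year mRS strictly below 3-month mRS
  (3-month mRS 0 or 6, or loss to 1-year follow-up, ineligible).
  Ineligibility is represented as missing, never as `False`.
* **Exposure** — `tmt_mean < Q25`, with Q25 computed by linear
  interpolation between order statistics (NumPy's `linear` quantile
  convention) on the full analysis cohort. Ties at the cutoff fall in the
  high group (strictly-below rule). The cutoff value and quantile
  convention are always emitted in a `CutoffSpec` so a convention change
  is visible in every output. The same machinery serves TMT/height²
  (mm/m²), the height-normalized sensitivity exposure.
* **Infarct volume** — % of total brain volume; missing values are
  replaced by the cohort median, with the imputation count reported.
* **END cause** — a registry label passed through, except that
  symptomatic haemorrhagic transformation is validated against the
  ≥ 4-point NIHSS rise it requires; violations are kept but logged.

## Effect estimation

Crude 2×2 odds ratios use the closed form ad/bc with the Woolf
(log-scale) interval `exp(log OR ± 1.96·√(1/a+1/b+1/c+1/d))`; a zero cell
triggers the Haldane–Anscombe 0.5 correction, flagged on the estimate.
Group comparisons use Pearson chi-square with a Fisher-exact fallback
when any expected cell is < 5, and Student's t versus Mann–Whitney for
continuous variables, dispatched by a D'Agostino normality screen
(p > 0.05 in both groups, n ≥ 20).

Adjusted effects come from logistic regression with a fixed covariate
list: age, sex, admission NIHSS, BMI, pre-stroke mRS, previous stroke,
hypertension, diabetes, hyperlipidaemia, atrial fibrillation, coronary
artery disease, smoking, stroke subtype (reference-coded against the
most frequent level, large-artery atherosclerosis), revascularization,
haemoglobin, total cholesterol, and (median-imputed) infarct volume.
Continuous-TMT effects are reported per 1 mm **decrease** by negating the
fitted coefficient.

### The logistic solver

One Newton solver serves both estimators. Maximum likelihood iterates
`β ← β + I(β)⁻¹ U(β)` with step-halving on the log-likelihood;
convergence is declared at score norm < 1e-8 (cap 100 iterations). The
**Firth** penalty maximizes the Jeffreys-prior penalized likelihood
`l*(β) = l(β) + ½ log det I(β)` by replacing the score with
`X'(y − μ + h(½ − μ))`, `h` the hat-matrix diagonal; step-halving then
monitors the penalized objective. Wald inference throughout (matching
the OR/CI reporting style); covariance is the inverse observed
information at the optimum.  For the exposure term of an adjusted model
two alternative intervals are available: a profile-likelihood CI
(inversion of the likelihood-ratio test via offset refits) and a
subject-resampling percentile bootstrap CI; both are useful when the
adequacy of the quadratic Wald approximation is in doubt.

Aliased design columns are removed by a greedy Gram–Schmidt rank screen
(tolerance 1e-8 on the normalized residual) and reported on the fit.
Separation handling distinguishes two situations: *complete* separation
(every observation perfectly predicted) or divergent non-convergence
aborts an ML fit with an error advising the Firth path; *quasi*
separation (an individual coefficient beyond ±15, e.g. a rare category
with no events, in an otherwise converged fit) is flagged but returned,
and the calling layers (interaction scans, mediation, ROI mapping)
respond by refitting with Firth. Subgroup models switch to Firth
pre-emptively when any exposure×modifier stratum has fewer than 8 events
or non-events — a concrete, logged stand-in for "rare event rates".

## Mediation

Dysphagia, END and post-discharge recovery are treated as **parallel**
binary mediators (independent given exposure and covariates). One
logistic model is fitted per mediator (`M_j ~ X + C`) and one for the
outcome (`Y ~ X + M₁..M_k + C`). Natural effects on the **risk-difference
scale**:

    TE  = E[Y(1, M(1))] − E[Y(0, M(0))]
    NDE = E[Y(1, M(0))] − E[Y(0, M(0))]
    NIE = E[Y(1, M(1))] − E[Y(1, M(0))]         (TE = NDE + NIE identically)
    NIE_j = E[Y(1, M_j(1), M_{−j}(0))] − E[Y(1, M(0))]

The risk-difference scale is used because "proportion mediated" is
ill-defined on the odds-ratio scale when the outcome is common (33–60%
event rates here). The counterfactual integrals over the mediator law
are evaluated **exactly** by enumerating all 2^k mediator combinations
(k ≤ 10); this removes Monte-Carlo noise from the point estimates and
makes the additivity identity hold to machine precision. A Monte-Carlo
path (`mc_draws > 0`) is retained and agrees with enumeration in tests.
Uncertainty comes from a percentile bootstrap over subjects (default 500
replicates; ≥ 200 for reported intervals) with every model refitted per
replicate; degenerate resamples (e.g. a constant mediator) are skipped
and counted. Proportion mediated = NIE/TE, reported only when the two
share a sign.

Candidate mediators pass an **entry screen**: the adjusted
exposure→candidate association and the adjusted candidate→outcome
association (controlling for exposure) must both be Wald-significant at
0.05. Post-discharge recovery is allowed as a mediator for the 3-month
outcome, mirroring the source design; note the temporal overlap caveat —
the mediator is resolved at the same horizon as the outcome, so this
channel is associational rather than strictly causal.

## ROI-wise lesion-interaction mapping

Atlases are merged by priority (default: brainstem > cortical > tract,
mirroring a brainstem/AAL/JHU stack): each voxel keeps the label of the
highest-priority atlas claiming it, provenance retained. Lesion burden
per merged ROI is `(lesioned voxels in ROI) / (brain voxels) × 100` — %
of total brain volume, the same scale as the total-infarct covariate, so
coefficients are comparable across ROIs. Voxel membership is binary; all
volumes must share one grid and affine (no resampling). Per ROI, one
logistic model contains the ROI burden, the exposure, their product and
the clinical covariates **minus total infarct volume** (collinear with
the burden regressor); p-for-interaction is the Wald test on the product
term at 0.05, deliberately without multiple-comparison correction (a
config switch can add Benjamini–Hochberg; default off). ROIs with no
lesioned subject are skipped; ROIs with < 5 lesioned subjects are fitted
with Firth and flagged low-support rather than dropped. Symmetric
left/right pairs can be pooled by summing burdens (midline ROIs map to
themselves), trading localization for power against bilateral effects.

## The synthetic cohort generator

The generator exists so that every downstream stage is testable without
any clinical data. It draws covariates to match the target cohort's
marginals — age ~ N(75.3, 6.1) reflected at 65; 50.5% male; sex-specific
height, smoking (75% male / 11% female) and haemoglobin; BMI ~ N(23.9,
3.3); TMT as a linear model in sex (+1.4 mm male) and age (−0.08 mm/y)
plus N(0, 1.92) noise truncated at 1 mm, reproducing the female/older
skew of the low-TMT group without claiming the unobserved joint
distribution; admission NIHSS as a zero-inflated (8.7%) rounded
log-normal with median 4 and IQR ≈ 2–6; infarct volume log-normal with
median 0.07% and IQR ≈ 0.02–0.42%, missing at the observed 2/600 rate;
1-year follow-up lost at 20/600.

Outcomes are drawn **top-down** from logistic models whose coefficients
live in `effect_sizes` (`"outcome|term"` keys): the exposure defaults
plant the adjusted ORs the analysis is designed to recover (dysphagia
1.89, END 2.75, in-hospital recovery 0.67, post-discharge recovery 0.56,
and a 3-month mRS ≥ 3 model with a direct exposure effect of 1.6 plus
mediator effects 2.0/2.5/0.45), with intercepts set near the observed
unexposed event rates and small age/severity/infarct slopes creating
genuine confounding. The raw record fields are then **constructed to be
exactly consistent with the drawn flags**: FOIS from the dysphagia flag;
NIHSS trajectories with qualifying increments injected at a random day
≤ 14 for END subjects (magnitude ≥ 4 when END₄ was drawn) and item-wise
monotone improvement otherwise; the discharge/3-month/1-year mRS sequence
built jointly from the drawn outcome and recovery flags. Consequently
the rule-based derivation reproduces the planted binaries without error,
which is what makes parameter-recovery tests well-posed. Two documented
edge cases: near-ceiling admission NIHSS can cap a planted ≥ 4-point
rise (such subjects are demoted from END₄ and never labelled sHT), and a
drawn recovery flag is infeasible for subjects dead or at mRS 5 by
3 months (rare; the derived flag is used downstream).

Lesions are single contiguous blobs grown voxel-by-voxel (6-connectivity,
uniformly random frontier) on a 20³ toy template (8 mm³ voxels, brain =
full grid), sizes log-normal with median 20 voxels; subjects with missing
registry infarct volume model the "no DWI" case and receive no mask.
Three toy atlases (midline brainstem-like, left/right cortical blocks,
overlapping tract slabs) exercise the priority merge. One global seed is
expanded into independent substreams (covariates / outcomes+trajectories
/ lesions) via `numpy` `SeedSequence.spawn`, so changing one stage leaves
the others bit-identical.

**What the generator does not emulate:** realistic neuroanatomy or lesion
topography, inter-covariate correlations beyond those stated (the source
tables do not constrain them), measurement error in TMT, NIHSS trajectory
shapes beyond the derivation rules, or informative missingness. Passing
tests therefore demonstrate that the *procedures* are correct and
well-calibrated under the planted generative structure — not that the
clinical conclusions transfer to any real cohort.

## Planted-signal strengths and problem sizes

Design power analyses (run before the corresponding checks were frozen)
chose the planted mapping signals: a single-ROI lesion×exposure
interaction of +16 log-odds per 1% brain burden (a typical in-ROI burden
of 0.1–0.3% ⇒ conditional OR ≈ 2–5 for an average lesion) yields ≈ 0.95
power at n = 2000; a bilateral +10-per-side signal is usually missed
side-by-side (both-sides power ≈ 0.2) but found after pooling (power
≈ 1.0). Under a global null the per-ROI Wald test runs mildly conservative at
this scale (the acceptance run measures the realized rate); calibration
is assessed as the mean per-cohort flagged fraction over 200 null
cohorts against the binomial bounds implied by that many cohorts. Parameter-recovery checks use n = 5000 with 100
replicates (END, planted OR 2.75); mediation checks use n = 3000 with
200 bootstrap replicates. These sizes were chosen as the smallest at
which the asymptotics under test are expected to hold cleanly.

## Known limitations

* Wald (not likelihood-ratio or score) inference everywhere, by design;
  Wald p-values for interaction terms on sparse burden regressors are
  conservative at moderate support and non-monotone for extreme effects
  (Hauck–Donner), and Firth-refitted Wald intervals after a separation
  trigger can be anti-conservative.
* The mediator set is treated as parallel; causally ordered mediators
  (dysphagia → END, say) would need a sequential decomposition that is
  out of scope.
* The exact penalized method behind the source's "penalized logistic
  regression" is not named there; Firth's is the assumption implemented.
* Whether the per-ROI lesion regressor should be absolute volume, % of
  brain, or % of ROI is not stated in the source; % of brain is the
  implemented, documented choice.
* The published cutoff (5.1 mm), adjusted ORs and mediation proportion
  (45.3%) require the original registry and imaging; the package can
  state them only as documentation examples, and its simulation-based
  checks target the *procedures*, with the published 2×2 tables as the
  exact numerical anchors.
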