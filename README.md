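# strokemap

Sarcopenia and stroke outcomes: a tested, reusable implementation of a
registry-style analysis of **temporal muscle thickness (TMT)** — an
MRI-measurable surrogate of sarcopenia — in elderly acute ischaemic
stroke patients.

Sarcopenia (age-related loss of skeletal muscle) worsens functional
outcome after stroke, but the *mechanisms* are hard to pin down in a
registry: they involve rule-derived intermediates (dysphagia, early
neurological deterioration, period-specific recovery), rare-event
subgroups, mediation, and lesion-location effect modification. This
package implements that entire analysis chain for biostatisticians and
stroke researchers who want to rerun it, audit it, or apply it to their
own cohorts:

* **Outcome derivation** from raw records under explicit rules:
  dysphagia = FOIS 1–6; END = NIHSS worsening within 3 weeks (total ≥ +2,
  consciousness 1a–1c ≥ +1, motor 5a–6b ≥ +1, or a new deficit), END₄ =
  total ≥ +4; in-hospital / post-discharge / chronic recovery with their
  eligibility exclusions; low TMT = mean TMT below the cohort 25th
  percentile, `low = 1{TMT < Q25}`.
* **Effect estimation**: 2×2 odds ratios `ad/bc` with Woolf intervals
  `exp(log OR ± 1.96·√(1/a+1/b+1/c+1/d))`; covariate-adjusted logistic
  models; a from-scratch Newton solver providing both maximum likelihood
  and **Firth's penalized likelihood** `l(β) + ½ log det I(β)` (finite
  estimates under separation); interaction-term subgroup scans.
* **Multi-mediator counterfactual decomposition** on the risk-difference
  scale — `TE = E[Y(1,M(1))] − E[Y(0,M(0))]` split into natural direct
  and indirect parts with `TE = NDE + NIE` exactly — with a
  subject-level percentile bootstrap.
* **ROI-wise brain mapping**: priority merge of labelled atlases, lesion
  burden per ROI as % of brain volume, one logistic interaction model
  per ROI (`burden + exposure + burden×exposure + covariates`), and
  pooling of symmetric left/right ROIs.
* A **synthetic cohort generator** that reproduces the study's marginal
  structure and plants known effects, so every stage above is testable
  end-to-end without patient data.

## Worked example

```python
import strokemap as sm

cfg = sm.SimulationConfig(n_subjects=600, seed=42)   # study-sized cohort
cohort = sm.simulate_cohort(cfg)
df, sidecar = sm.analysis_frame(cohort)              # derive all outcomes
print(round(sidecar["cutoff_tmt"]["value"], 2), sidecar["n_low_tmt"])

est, fit = sm.adjusted_effect(df, "low_tmt", "end")  # adjusted OR for END
print(f"{est.or_point:.2f} ({est.ci_low:.2f}-{est.ci_high:.2f})")

from strokemap.mediation import MediationSpec, mediate, mediator_entry_screen
covs = ["age", "sex", "admission_nihss"]
admitted, _ = mediator_entry_screen(
    df, ["dysphagia", "end", "postdischarge_recovery"], covariates=covs)
res = mediate(df, MediationSpec(mediators=admitted, n_boot=200, seed=42,
                                covariates=covs))
print(res.to_frame().round(3))
```

prints

```
5.36 150
2.30 (1.36-3.89)
             effect  estimate  ci_low  ci_high
              total     0.086   0.009    0.172
             direct     0.064  -0.012    0.149
  indirect_combined     0.022   0.003    0.044
      indirect[end]     0.022   0.003    0.044
proportion_mediated     0.257   0.071    1.013
```

Reading this: the generator dichotomized TMT at its in-sample 25th
percentile (5.36 mm, 150/600 subjects low). The covariate-adjusted odds
ratio of low TMT for early neurological deterioration is 2.30
(CI 1.36–3.89), recovering the planted effect of 2.75 within its
interval. At n = 600 only END survives the mediator entry screen (both
exposure→mediator and mediator→outcome associations significant at
0.05); the decomposition attributes 0.022 of the 0.086 risk difference
for poor 3-month outcome (mRS ≥ 3) to the END pathway — about 26%
mediated, with a wide bootstrap interval at this sample size.

The same stages are available from the shell:

```bash
strokemap simulate --n 600 --seed 42 --out run/
strokemap derive --cohort run/cohort.csv --exams run/nihss_exams.csv --out run/derived
strokemap report --seed 42 --out run/full   # full pipeline + manifest
```

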