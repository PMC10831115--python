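# chemoresilience

Predicting **chemotherapy non-resilience** from digital frailty biomarkers
captured by a pendant-worn activity sensor.

Patients starting a bi-weekly chemotherapy cycle wear a pendant accelerometer
continuously for the 14 days between infusions. From the second-resolution
posture stream (lying / sitting / standing / walking) and step events, nine
daily biomarkers of frailty phenotypes are derived: walking cadence (90th
percentile of steps/min — *slowness*), sit-to-stand and stand-to-sit counts
(*weakness*), steps in the longest unbroken walking bout (*exhaustion*),
total daily steps and the four posture-time percentages (*inactivity*).
Patients are labelled **non-resilient** if they experience dose reduction or
discontinuation, a cancer-related hospitalization within 4 weeks, or death
within 6 months of therapy start; otherwise **resilient**.

This package implements the full analysis pipeline as a tested library plus
CLI, with a synthetic-cohort generator standing in for the (non-public) raw
sensor data:

* **`chemoresilience.cohort`** — synthetic cohorts: Table-2-style covariates
  (age, sex, BMI, ECOG), outcome flags, a latent piecewise-linear
  functional-capacity trajectory (nadir on day 2–3, resilient recovery by
  ~day 6, non-resilient plateau/late decline), semi-Markov posture/step
  streams, and optional raw 50 Hz tri-axial accelerometry.
* **`chemoresilience.biomarkers`** — the nine daily biomarkers, plus a
  documented posture/step classifier for the raw-signal tier.
* **`chemoresilience.trajectories`** — the trajectory statistic
  `(endpoint − baseline) / baseline`, Welch t-tests and pooled-SD Cohen's *d*
  per feature and day.
* **`chemoresilience.model`** — logistic regressions (ECOG, MBF, ECOG+MBF),
  the earliest monitoring day with in-sample AUC ≥ 0.80, the
  **Chemotherapy Resilience Index** (CRI = fitted probability of
  non-resilience, 0–1), Youden-optimal cut-point metrics, and the
  prevalence-adjusted PPV

  ```
  adjPPV = sens·prev / (sens·prev + (1 − spec)(1 − prev))
  ```

## Worked example

One command simulates a 27-subject cohort (14 resilient / 13 non-resilient),
extracts biomarkers and runs the full analysis:

```bash
chemoresilience run --seed 1 --out demo/
```

prints (abridged):

```
Per-day MBF AUC: d2=0.64, d3=0.73, d4=0.84, d5=0.75, d6=0.76, d7=0.91, ...
Earliest day with AUC >= 0.80: day 4
Model AUCs: ECOG=0.64, MBF=0.84, ECOG_MBF=0.85
CRI (resilient 0.29 +/- 0.27 vs non-resilient 0.68 +/- 0.25, p = 0.00068, d = 1.49)
Optimal CRI cut-off 0.55: sensitivity 77%, specificity 79%, PPV 77%, adjusted PPV 77% (prevalence 48%)
```

Reading: the sensor-only (MBF) logistic model, using day-4 relative changes
in cadence and postural transitions, already separates the groups
(AUC 0.84) in this particular small cohort — with n = 27 the per-day AUC
curve is noisy, which is why the earliest qualifying day fluctuates around
the mid-cycle at this sample size (at n = 200 it concentrates on days 5–7).
The combined ECOG+MBF model's fitted probabilities are the CRI: group means
0.29 vs 0.68 with a very large effect size, and the Youden-optimal threshold
0.55 classifies non-resilient patients with 77% sensitivity and 79%
specificity. `demo/` contains the subjects/biomarker tables, per-day AUCs,
model coefficients, per-subject CRI, cut-point metrics (`results.json`) and
a provenance copy of the configuration; add `--report` for figure files.

The same steps are available piecewise (`chemoresilience simulate`,
`extract`, `analyze`) and as library calls:

```python
import chemoresilience as cr

subjects, biomarkers = cr.simulate_tables(cr.CohortConfig(n_subjects=200, seed=1))
search = cr.earliest_day_search(biomarkers, subjects)        # per-day AUCs
fits = cr.compare_models(biomarkers, subjects, day_index=6)  # ECOG / MBF / combined
cut = cr.optimal_cutpoint(fits["ECOG_MBF"].cri_scores,
                          (subjects["group"] == "nonresilient").to_numpy())
```

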