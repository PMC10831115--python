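# Methods

## Outcome definition and study design being emulated

A monitoring window opens on the first day of a bi-weekly chemotherapy cycle
and closes 14 days later, before the next infusion. Day 1 is the baseline.
A subject is *non-resilient* if at least one of three adverse events occurs:
dose reduction or discontinuation, cancer-related hospitalization within
4 weeks of therapy start, or death within 6 months; the group label is
defined by (and validated against) these flags. ECOG performance status is
carried both as the 0/1/2 grade and dichotomised (0 vs 1–2) for modelling.

## Daily biomarkers

All nine features are computed per consecutive 24 h block from monitoring
start (not calendar-midnight days):

* **cadence_p90** — 90th percentile (linear interpolation) of per-minute
  step counts over *walking minutes*, i.e. calendar minutes containing at
  least one walking second. A day with no walking has cadence 0 by
  convention, and its trajectory ratio is flagged missing rather than
  divided by zero.
* **n_sit_to_stand / n_stand_to_sit** — transitions between collapsed
  posture runs, with walking treated as upright: a walking interlude between
  standing blocks creates no transition, and sitting→walking counts as one
  sit-to-stand. This edge-case convention is ours; the transition counts on
  unambiguous streams are exact.
* **longest_bout_steps** — steps inside the longest walking episode, where
  non-walking interruptions up to `max_gap_s` (default 3 s) do not break the
  bout. "Unbroken" has no standard definition; 3 s tolerates a brief pause
  without merging distinct walks.
* **total_steps**, and the four posture-time percentages of the 24 h day
  (they sum to 100 by construction).

Percentages of a *partial* day (stream shorter than 24 h) are computed over
the observed duration only when the caller passes an explicit flag;
otherwise short streams are an error. An optional MET-based energy
expenditure (1.0/1.3/1.8/3.0 MET for lying/sitting/standing/walking) is
provided but excluded from the default feature set.

## Trajectory statistic and group contrasts

Each biomarker's trajectory is summarised as
`(endpoint − baseline) / baseline` (endpoint = last monitored day). Group
contrasts use Welch's two-sample t-test — chosen over the pooled-variance
variant because group SDs are typically unequal in such cohorts; a
pooled-variance option exists. Cohen's *d* uses the pooled, (n−1)-weighted
SD, signed resilient-minus-non-resilient. Day-wise tests are reported
per (feature, day) cell without multiple-testing correction by default,
matching the per-day-asterisk reporting style this analysis emulates;
Benjamini–Hochberg flags are available opt-in.

## Models, CRI, cut-point

Three logistic regressions of non-resilience are fitted by maximum
likelihood (statsmodels): dichotomised ECOG alone; the mobility biomarker
set (MBF); and both. MBF predictors default to the day-*d* **relative
change from baseline** of cadence_p90 and of total postural transitions
(sit-to-stand + stand-to-sit combined into one predictor; separable by
config). Change-from-baseline was chosen over raw day-*d* levels because
the scientific object is the response to chemotherapy, not the
between-subject activity level; a raw-value mode is available. Perfect or
quasi-separation (non-convergence, or |linear predictor| > 30) is detected
and refitted with a small ridge penalty (α = 1e-4, intercept unpenalised,
Newton iterations), always flagged — fitted probabilities are then
saturated and coefficients regularised rather than true MLEs.

The **CRI** is the combined model's fitted probability of non-resilience.
The earliest-day search fits the MBF model for each candidate day 2..14 and
returns the first day whose **in-sample** AUC (Mann–Whitney, ties ½)
reaches 0.80. In-sample evaluation mirrors the small-sample practice this
pipeline reproduces and is an acknowledged optimism source; there is no
train/test split by default.

The operating threshold maximises Youden's J over observed scores with the
rule *score ≥ threshold → non-resilient*; J-ties resolve to the higher
threshold (higher specificity). PPV = TP/(TP+FP); the adjusted PPV is the
Bayes form `sens·prev / (sens·prev + (1−spec)(1−prev))` with prevalence
defaulting to the sample positive fraction (overridable for external
populations). At the sample prevalence the two coincide algebraically,
which the tests verify numerically.

## Synthetic cohort generator

No public sensor data exist for this design, so cohorts are simulated.

**Latent capacity.** Each group has a piecewise-linear capacity multiplier:
1.0 at day 1, linear descent to `1 − nadir_depth` at `nadir_day`, linear
recovery to `plateau_level` at `recovery_day`, then drift at `late_slope`
per day. Defaults: resilient (nadir day 3, depth 0.30, full recovery by
day 6), non-resilient (nadir day 3, depth 0.40, plateau 0.70, −0.01/day
after day 6) — the qualitative pattern of an early nadir, resilient
recovery by mid-cycle, and non-resilient failure to recover.

**Daily activity.** A day is a bout sequence: a 23:00–07:00 lying block,
then sit/stand cycles hosting walking bouts, with an optional nap whose
probability rises as capacity falls. Expected daily steps and sit↔stand
cycle counts scale *linearly* with capacity m; walking cadence scales with
√m (speed declines less than volume), so expected walking time scales with
√m — the three cannot all be linear since steps = time × cadence, and the
linear-volume/compressed-cadence choice is the one the simulated recovery
narrative needs. Baselines are ECOG-graded (6500/4200/2800 steps/day,
cadence 95/85/75 steps/min, 45/38/30 cycles/day for ECOG 0/1/2) with
lognormal subject heterogeneity (CV 0.20/0.05/0.15).

**Noise.** One dial, `noise_sd`, sets the day-to-day lognormal CV of step
volume; cadence and cycle-rate day noise are 0.48× and 0.40× of it. The
default 0.38 was calibrated once so that, at n = 200, the day-6 MBF model
clears AUC 0.80 while days ≤ 4 do not — i.e. so the generator reproduces
the mid-cycle separability the design describes — and is not a free
parameter of the analysis. Day-to-day step CVs near 0.4 are within the
range reported for free-living older adults.

**Covariates and outcomes.** Age, BMI (truncated 15–50 kg/m²), sex and the
ECOG distribution are drawn per group from the emulated cohort's summary
statistics; adverse-event flags for non-resilient subjects use marginal
rates 0.54/0.62/0.85 (dose/hospitalization/death), redrawn until at least
one is set. Group assignment is stratified (exact counts), so the default
27-subject cohort is exactly 14/13. One master seed spawns per-subject,
per-day child streams: cohorts are extensible without reshuffling history,
and identical configs are bit-identical.

**Raw-signal tier.** Optionally each day is rendered to 50 Hz tri-axial
waveforms: gravity in a posture-specific trunk orientation (5° standing,
10° walking, 20° sitting, 90° lying), one vertical sinusoid period per step
(amplitude 0.35 g), white noise (default SD 0.05 g). The classifier inverts
this: per-second mean vector → inclination (lying > 45°), band-passed
(0.5–3 Hz) trunk-axis RMS → walking, a static-tilt rule (12°) separating
sitting from standing, and step detection by peak prominence. It is a
simple documented stand-in for proprietary device firmware, *matched* to
the generator's signal model — round-trip accuracy (≥ 95% labels, ≤ 5%
steps) certifies internal consistency of the tier, not performance on real
hardware.

## What the synthetic experiments do and do not show

Passing tests demonstrate that the pipeline recovers, from data generated
under its own stated assumptions, the qualitative structure it targets:
mid-cycle earliest-detection day, sensor models outperforming ECOG alone,
large CRI group separation, nominal type-I error on null cohorts. They do
not validate the biomarkers or the CRI on real patients: the generator has
no wear-time artifacts, no missing days by default (a masking option
exists), independent day-to-day noise (no autocorrelation beyond the latent
trajectory), and group differences injected exactly through the two
channels the model uses. Real-data headline values (specific AUCs, CRI
means, the 0.54 cut-off) are therefore not exact reproduction targets at
n = 27; only the worked arithmetic (e.g. the adjusted-PPV 83% at
sensitivity 10/13, specificity 12/14, prevalence 13/27) is exact.

## Problem sizes and numerical choices

Simulation-based checks use n = 200 cohorts over 10 fixed seeds for the
earliest-day bound, 200 cohorts of n = 40 for null calibration, and a
10-subject-day batch for the raw-signal round trip — sizes chosen to make
Monte-Carlo noise small relative to the asserted tolerances. Percentile =
NumPy linear interpolation; probability clipping at |η| ≤ 30 for separation
detection; activity days are stored run-length encoded with the dense
86 400-label vector materialised on demand, and the extractors are
property-tested against exhaustive dense-scan oracles.

## Known limitations

In-sample AUC optimism (by design, matching the emulated analysis); the
classifier tier's circularity noted above; printed effect sizes from small
real cohorts are not reproducible to the digit under any standard Cohen's-d
convention, so they are treated as approximate anchors; no survival
modelling of the mortality endpoint; no alternative classifiers.
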