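# promthresh

Anchor-based estimation of success and failure thresholds for
patient-reported outcome measures (PROMs) after total knee arthroplasty
(TKA).

## The problem

Comparing TKA results by mean or median PROM scores blurs clinical
significance. An alternative is to dichotomize an external *anchor* — here
the final item of the Goodman satisfaction scale, "How much did your knee
surgery improve your quality of life?" on a six-level Likert scale — into
**failure** ("same or worse", responses 1–4) versus **success** ("much
better", responses 5–6), and then find the PROM score at which a patient's
probability of failure departs significantly from the cohort's baseline
rate. The resulting cutoffs are the **threshold for increased success
(TIS)** and the **threshold for increased failure (TIF)**, usable for
sample-size calculations and success/failure-rate comparisons where
PASS/MCID-style thresholds are unavailable.

## The model

For each instrument (WOMAC-Pain 0–20, WOMAC-Stiffness 0–8, WOMAC-Function
0–68, all lower-is-better; Kujala 0–100 and KOOS-QL 0–100,
higher-is-better), a univariable logistic regression of failure on the
score x:

```
logit P(failure | x) = β₀ + β₁x
```

The coefficient covariance Σ is estimated by case-resampling bootstrap
(B = 200 refits by default; the observed-information covariance is
available as an alternative). The failure probability
p(x) = expit(β₀ + β₁x) receives a pointwise 95% confidence band at every
integer score via the delta method on the probability scale:

```
Var p(x) ≈ gᵀΣg,   g = p(1−p)·(1, x),   band = p ± 1.959964·√Var, truncated to [0,1]
```

Scanning from the instrument's good extreme, TIS is the first score where
the band stops lying entirely below the baseline failure proportion
p₀ = n_failure/n; TIF mirrors it from the bad extreme with the band
entirely above p₀. Bounds are reported with strict relations ("<4" means
scores 0–3 qualify). Discrimination is graded by tie-aware ROC AUC with a
stratified bootstrap percentile CI and the five-level scale
(<0.6 low, 0.6–0.69 discrete, 0.70–0.79 moderate, 0.80–0.89 good,
≥0.9 excellent).

Because patient-level study data are not deposited, the package ships a
seeded synthetic-cohort generator (`synthetic_cohort`) that reproduces the
study conditions — 161 procedures, five bounded integer instruments,
outcomes drawn through a known logistic link with an expected failure rate
of 21/161 ≈ 13% — so every stage of the pipeline is testable against known
ground truth.

## Worked example

```python
from promthresh import (
    make_paper_like_cohort, run_prom_analysis, baseline_probability,
    BUILTIN_PROMS, AnalysisSettings,
)

cohort = make_paper_like_cohort(seed=7)
base = baseline_probability(cohort)
print(f"cohort: n={base.n}, failures={base.n_failure} ({base.percent})")

res = run_prom_analysis(cohort, BUILTIN_PROMS["womac_pain"], AnalysisSettings(seed=1))
thr, roc = res.thresholds, res.roc
print(f"WOMAC-Pain TIS {thr.format_bound('tis')}  TIF {thr.format_bound('tif')}")
print(f"P(TIS) = {thr.p_tis:.3f} ({thr.p_tis_ci[0]:.3f}-{thr.p_tis_ci[1]:.3f})")
print(f"P(TIF) = {thr.p_tif:.3f} ({thr.p_tif_ci[0]:.3f}-{thr.p_tif_ci[1]:.3f})")
print(f"AUC    = {roc.format()} [{roc.category.value}]")
```

prints

```
cohort: n=161, failures=18 (11.18%)
WOMAC-Pain TIS <3  TIF >5
P(TIS) = 0.043 (0.003-0.084)
P(TIF) = 0.279 (0.153-0.404)
AUC    = 0.83 (0.74-0.91) [good]
```

Reading: in this synthetic cohort 18 of 161 knees (11.18%) report "same or
worse" quality of life. A WOMAC-Pain score below 3 lowers the failure
probability significantly below that baseline (to 4.3%, CI 0.3–8.4%), a
score above 5 raises it significantly (to 27.9%, CI 15.3–40.4%), and the
score discriminates failures from successes with good accuracy
(AUC 0.83).

The same analysis is available from the shell:

```sh
promthresh simulate --config examples/generator.yaml --out cohort.csv
promthresh analyze --input cohort.csv --boot 200 --seed 7 --out report/
promthresh validate --scenarios examples/scenarios.yaml --seed 1 --out summary.tsv
```

`analyze` writes `thresholds.tsv`, `probabilities.tsv`, one cumulative-
frequency TSV per instrument, and a `manifest.json` that records the full
configuration, seed, attrition and bootstrap convergence counts; reruns
with the same seed are byte-identical.

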