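# Methods

## Outcome definition

The modeled event is *failure to improve quality of life*: a response of
1–4 ("worse" through "moderate improvement") on the six-level anchor item
"How much did your knee surgery improve your quality of life?". Responses
5–6 map to success. Failure is the positive class everywhere — fitted
probabilities, thresholds and AUCs all refer to the probability of "same
or worse". The baseline probability p₀ is the cohort-wide failure
proportion (exact fraction n_failure/n; rendered to two decimals as a
percentage, three decimals as a probability).

Missing data policy: a record without an anchor response cannot contribute
an outcome and is dropped (the count is logged and recorded in the
manifest); a record missing one instrument's score stays in the cohort and
is simply excluded from that instrument's complete-case analysis. No
imputation is performed.

## Logistic fit

Each instrument is analyzed marginally:
logit P(failure|x) = β₀ + β₁x with x the raw integer score. The MLE is
computed by Newton–Raphson/IRLS with step-halving; halving is skipped for
log-likelihood decreases within float round-off of ℓ (≤1e-10·(1+|ℓ|)),
which would otherwise trap the iteration in a limit cycle at the optimum.
Convergence requires |Δℓ| < 1e-10 and gradient norm < 1e-8. Separation is
declared when |β| exceeds 30 on the logit scale or 100 iterations pass
without convergence; single-class or constant-score inputs are rejected
up front. The information covariance is the inverse observed information
at the MLE.

## Coefficient covariance

The default covariance is an unstratified case bootstrap: B = 200
resamples of (score, outcome) pairs with replacement, each refit by the
same IRLS; resamples that fail (separation or a lost outcome class) are
skipped and counted, and the covariance is the empirical covariance of the
converged coefficient pairs. At least B/2 converged resamples are
required, otherwise the analysis errors rather than report a covariance
built from a handful of refits. B = 200 reflects the resampling depth the
method was designed around; it is configurable. The information covariance
is available as `cov_source=model_information` and agrees with the
bootstrap at large n under a correctly specified link — note that on data
whose outcome rates are *not* logistic in the score, the case bootstrap
consistently estimates the robust sandwich covariance instead, which is
the behavior one wants for threshold inference on real cohorts.

Every stochastic operation takes an explicit seed and uses numpy's
default PCG64 generator; the `analyze` command derives per-instrument
seeds from the master seed with a fixed stride (7919) so the streams are
independent but fully reproducible.

## Probability band and threshold rule

For every integer score x in the instrument's full range (not just
observed values, so bounds are reproducible), p(x) = expit(β₀ + β₁x) and
the delta method on the probability scale gives
Var p ≈ gᵀΣg with g = p(1−p)(1, x); the 95% band is p ± 1.959964·√Var,
truncated to [0,1]. A logit-scale variant (normal band for η mapped
through expit) is available for sensitivity analysis; the two agree to
first order and differ by a term of order (z·se_η)²·p(1−p)(1−2p)/2, which
matters only when se_η is large (small cohorts, extreme scores).

Thresholds: let the *good* extreme be the minimum score for
lower-is-better instruments and the maximum for higher-is-better ones.
The TIS region is the maximal contiguous run of scores starting at the
good extreme with upper95 < p₀; the TIS bound is the first score outside
that run, reported with a strict relation ("<" or ">" by orientation),
and the quoted probability p_TIS (with CI) is taken at the qualifying
score adjacent to the bound. TIF mirrors this from the bad extreme with
lower95 > p₀. Requiring contiguity from the extreme makes "first value
where the CI excludes p₀" well defined and clinically monotone: isolated
interior excursions of the band (possible because its width varies with
x) do not create thresholds. An empty run is a valid result — the bound
is reported as absent. The rule does pointwise comparisons at every grid
score, so its family-wise error over the grid is not controlled; the
null-slope false-threshold rate is reported as a diagnostic by the
`validate` command rather than asserted against a bound.

## Discrimination

AUC is the Mann–Whitney statistic with average ranks (half-credit for
ties), computed on risk-oriented scores (higher-is-better instruments are
negated first, so a discriminating instrument reports AUC ≥ 0.5). The
95% CI is a stratified bootstrap percentile interval (resampling within
each outcome class, B = 200 by default). Grading uses half-open bins,
total on [0,1]: [0,0.6) low, [0.6,0.7) discrete, [0.7,0.8) moderate,
[0.8,0.9) good, [0.9,1] excellent; 0.90 is graded excellent.

## Synthetic cohorts

Scores are drawn from a normal distribution truncated to
[min−0.5, max+0.5] and rounded, giving bounded integers with a unimodal
marginal whose location/spread are per-instrument parameters; spread 0
degenerates to a point mass. Outcomes are Bernoulli through the logistic
link in a designated outcome instrument's realized score. In multi-
instrument cohorts the other instruments load on a shared latent severity
factor (weight w, default 0.75 in the study-like cohort) with a sign
matching their orientation, so each correlates with the outcome the way
concurrently administered questionnaires do while only one score drives
the link exactly.

The study-like cohort fixes n = 161 and calibrates the intercept by
root-finding so the expected failure count over the realized scores is
exactly 21/161 ≈ 13.04%; observed counts then vary binomially across
seeds. Score locations (pain 3.0±3.5, stiffness 1.0±1.6, function
9.0±9.0, Kujala 73±15, KOOS-QL 62±20) were chosen once to match the
qualitative shape of post-TKA cumulative-frequency curves — most knees
near the good end of every scale; the true study marginals are
unpublished, so these are explicit stand-ins and no result depends on
their specific shape. What passing tests on these cohorts demonstrate is
that the *estimator and rule* recover known truth under the assumed
model; they cannot validate the clinical thresholds themselves, which
require real patient data.

## Validation harness and problem sizes

`validate` (and the test suite) replicate the single-instrument layout
with known coefficients and summarize: Wald coverage of each coefficient;
the rate at which TIS and TIF are both present and bracket the true
crossing score x* (expit(β₀+β₁x*) = p₀, using each replicate's observed
p₀), counted strictly — an absent bound fails the replicate; and the
threshold-absence rate under β₁ = 0. The reference scenario is n = 5000,
β = (−4.0, 0.30), pain-like scores 8.0±4.0, 200 replicates — large enough
that coverage and bracketing rates are stable to a few percent while the
whole simulation runs in seconds. The delta-method band is checked
against a 100,000-draw parametric bootstrap (coefficients resampled from
N(β̂, Σ)) at the same n, with a 0.005 absolute tolerance on probability
endpoints covering Monte-Carlo error plus the first-order linearization
gap between the probability-scale band and the percentile band.

## Known limitations

- Univariable models only; no covariate adjustment, no ordinal modeling of
  the full six-level anchor, no MCID estimation.
- The threshold rule's grid-wide multiplicity is uncontrolled (inherent to
  the "first value where the CI excludes p₀" construction).
- The probability-scale delta band can truncate at 0/1 in small cohorts;
  the logit-scale variant avoids this at the cost of asymmetric bands.
- Synthetic score marginals are stand-ins; only one instrument per cohort
  carries an exactly logistic link, the rest are linked through the latent
  factor.
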