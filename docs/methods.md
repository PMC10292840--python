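# Methods

## Effect-size harmonization

All effects are pooled on the raw correlation scale, not Fisher-z. The raw
scale is what makes the two-study worked example meaningful: its robust
confidence interval extends far outside [−1, 1], which a z-scale analysis
would forbid. Group-difference statistics are converted with the standard
d↔r mapping for a two-group (young vs old) design,

    r = d / sqrt(d^2 + a),     a = (n1 + n2)^2 / (n1 n2),

with a delta-method sampling variance built on
var_d = (n1+n2)/(n1 n2) + d^2 / (2(n1+n2)). A t statistic is first mapped to
d = t sqrt(1/n1 + 1/n2). Note that the direct `t_to_r(t, df)` form
`t/sqrt(t^2+df)` agrees with the d-route exactly only at df = n1+n2; the two
routes are kept distinct and their consistency is property-tested at that
df. Pearson correlations from continuous-age designs use the large-sample
variance (1−r^2)^2/(n−1). Direction coding is enforced by `orient`: positive
always means the trait increases with age. Extreme-group comparisons use
only the youngest and oldest groups; tables containing intermediate-group
columns are rejected rather than silently pooled.

The age span of a sample is expressed in decades between the old and young
reference ages, where a group's reference age is its mean if reported and
the midpoint of its age range otherwise (18–30 ⇒ 24).

## Three-level REML model

The marginal covariance of the k effect sizes is

    M(tau^2, sigma^2) = V(rho) + tau^2 Z3 Z3' + sigma^2 I,

where V(rho) is the block-diagonal sampling covariance with within-study
correlation rho (default 0.5; the 0.1–0.9 grid is a one-call sensitivity
report) and Z3 indicates studies. The REML objective profiles beta out;
optimization runs L-BFGS-B from three starts (the origin, a
DerSimonian–Laird method-of-moments split, and a data-scale point), is
polished by Nelder–Mead, then by an analytic-gradient L-BFGS-B pass, and
finally by projected Newton steps on the analytic gradient. The last stage
matters: near the optimum the likelihood is flat to machine precision, so
line searches cannot localize the maximum, while root-finding on the
gradient pins the components to ~1e-11 — tight enough to match the
two-study closed form (pooled = mean, total heterogeneity
max(0, (y1−y2)^2/2 − v)) to 1e-10. Boundary solutions (components exactly
zero) are admissible; with one estimate per study only tau^2 + sigma^2 is
identified and the pseudo-inverse Newton solve simply stops moving along the
flat ridge, which leaves beta and all inference unaffected. Fitting is fully
deterministic.

The implementation was cross-checked against metafor's `rma.mv` (the
reference R implementation of this model) on a fixed 8-record/3-study
dataset; coefficients, model SEs, both variance components and Q agree to
at least 1e-6, and those values are frozen in the test suite.

## Cluster-robust inference

Model-based SEs understate uncertainty when the working covariance is
wrong, so all headline inference is CR2-type cluster-robust, clustered on
study. Cluster residuals are inflated by adjustment matrices A_j solving
A_j (Phi_j − X_j M X_j') A_j' = Phi_j (computed via symmetric square roots
in the Phi-metric), which makes the sandwich unbiased under the working
model. Per-coefficient degrees of freedom use a Satterthwaite approximation
evaluated under the fitted covariance; df is floored at 1 and a warning is
attached below 4. In the two-study worked example this yields df = 1 and a
t interval of [−6.66, +6.29] around a pooled r of −0.19 — enormous by
design, not by accident. Simulation checks in the test suite confirm ~95%
coverage of robust CIs at s = 60 studies and near-nominal type-I error for
the robust Egger test at s = 15.

Cochran's Q is the weighted residual sum of squares of the fixed-effects
GLS fit under V(rho) alone, df = k − p.

## Equivalence testing

TOST against symmetric bounds, default r = |0.1| (a conventional "small"
correlation, typical of individual-differences work), alpha = 5%. The test
statistics are z ratios on the robust SE; t-referenced p-values with the
robust df are reported alongside as the conservative variant. The verdict
"equivalent" requires both one-sided rejections and coincides exactly with
the 90% CI lying inside the bounds; "not_equivalent" means the 90% CI lies
wholly outside them; anything else is "inconclusive". Distinguishability
from each bound separately is reported because an estimate can clear the
lower bound yet be indistinguishable from the upper one.

## Cumulative meta-analysis and history

Year-wise accumulation is primary (all effects with year ≤ cutoff enter
together); study-wise traces order studies by (first publication year,
study id), a deterministic rule because within-year ordering changes the
shape of the trace. Each step is a full refit; single-study steps report
model-based CIs with robust inference marked unavailable, and step failures
are recorded in the trace rather than raised. The final step is
field-identical to the full-dataset fit by construction and by test.

The Proteus statistic compares the earliest study (ties broken by study id)
with the remainder: z = (m_rest − y_first)/sqrt(v_first + vbar_rest), where
multi-estimate studies enter via their unweighted within-study mean effect
and mean variance. The sign convention (rest minus first) makes an extreme
negative first study yield a positive z. Historical trends are a
meta-regression on (reference_year − year)/10, an OLS of log study n on
year (one n per study: its largest record, since estimates share
participants), and an OLS of citations/year on log n and mean |r|. OLS is
used for the citation model as the simplest defensible choice; count models
are a possible refinement.

## Publication-bias battery

The headline small-study-effect test puts sqrt(var_r) in the three-level
model as a moderator with robust inference (a multilevel PET variant),
because classical Egger regression assumes independent effects; the
classical weighted version is emitted alongside for comparability. Designs
with all-equal variances are refused (the SE column is collinear with the
intercept). The p-curve uses two-sided p from z = r/sqrt(var_r); significant
effects enter as pp = p/.05, right-skew is the Stouffer combination of
Phi^{-1}(pp) (small pp ⇒ negative z ⇒ evidential value, lower-tail p), and
flatness recomputes pp under a 33%-power noncentral alternative
(upper-tail p; the half-p-curve refinement is deliberately omitted in favor
of the canonical simple variant).

## Synthetic literatures

The generator draws study effects mu + trend·(year−ref)/10 + N(0, tau^2),
estimate deviations N(0, sigma^2), and correlated within-study sampling
errors on the raw-r scale with variance (1−theta^2)^2/(n−1), truncating by
resampling to keep |r| < 1. Default components tau^2 = 0.02,
sigma^2 = 0.01 represent moderate heterogeneity on the correlation scale;
preset study/effect counts, year spans and sample-size ranges mirror the
four real literatures (e.g. time preference has very large online samples,
effort has seven small lab studies). One-sided censoring drops
nonsignificant negative effects with a configurable probability, which is
the mechanism the Egger power checks exercise; the planted extreme first
study (r = −0.72, SE 0.22 in the time preset) reproduces the Proteus
scenario. Each study has its own seeded substream, so adding studies never
perturbs existing ones and traces are stable fixtures.

What the generator does *not* emulate: real moderator–effect confounding
beyond user-specified additive shifts, overlapping cohorts across studies
(study ids are treated as independent clusters), non-normal random effects,
and rounding/reporting error in extracted statistics. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated model, not that any real literature satisfies that model.

## Numerical choices and degenerate inputs

- REML convergence: multistart + gradient polish; accepted optimum must not
  lose more than 1e-12 log-likelihood against any candidate.
- Components bounded in [0, 20·max(var(y), mean(v))].
- Robust df floored at 1; equal-variance Egger designs, single-study robust
  requests, s < 3 influence/Proteus, and single-year trend regressions are
  refused with explanatory errors rather than returning numbers.
- Problem sizes in tests: recovery/calibration simulations use 200
  replicates at s = 60×3 (recovery), 500 at s = 15×2 (Egger), 100–300 for
  p-curve nulls — large enough for the stated tolerance bands while keeping
  the full suite in the minutes range on one core.

## Known limitations

Citations are an input column, not scraped; no trim-and-fill or selection
models; no Bayesian estimation, four-level structures, or network
meta-analysis; moderators enter meta-regressions singly, without
interactions, matching the analysis design the package implements.
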