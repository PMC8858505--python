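# Methods

## The problem

Regulators and trialists often need a treatment-effect estimate in a
subgroup too small to support a precise standalone analysis — here, the
young children (< 14 kg) in a non-inferiority trial comparing a
dolutegravir (DTG)-based antiretroviral regimen with standard of care
(SOC), where the bulk of the evidence comes from 707 older children and
only 85 young children are enrolled. Ignoring the older children wastes
information; pooling everyone assumes the treatment effects are identical.
`subborrow` implements the middle road: a *commensurate prior* that borrows
a controlled, elicitation-justified amount of information from the larger
subgroup.

## Model

Let the target (small) subgroup provide an estimate `y1` of its true risk
difference `theta1` with standard error `sigma1`, and the source (large)
subgroup provide `y0` for `theta0` with `sigma0`:

    y1 ~ N(theta1, sigma1^2)        y0 ~ N(theta0, sigma0^2)
    theta1 = theta0 + delta,        delta  ~ N(0, sigma_delta^2)
    theta0 ~ N(0, 10^6)             (flat)

`delta` is the treatment-by-subgroup interaction; `sigma_delta` (the
commensurability parameter) encodes how similar the two true effects are
believed to be. The prior mean of `delta` is fixed at zero so that expert
opinion can change the *weight* of the borrowed data but never relocate the
estimate. Both standard errors are treated as fixed and known; no
allowance is made for their sampling uncertainty.

The model is conjugate. In the flat-prior limit the posterior for `theta1`
is normal with

    mean = [ y1/sigma1^2 + y0/(sigma0^2 + sigma_delta^2) ] / P
    var  = 1 / P,   P = 1/sigma1^2 + 1/(sigma0^2 + sigma_delta^2)

`posterior_combine` implements exactly this closed form, so the posterior
precision is additive by construction. The proper `N(0, 1e6)` prior is
honoured by the test oracle, which integrates the full two-parameter model
on a dense 2-D grid; closed form and grid agree to four decimals, and the
grid posterior moves by less than 1e-6 when the prior variance is raised to
1e9, which is why the flat limit is safe.

### Relative weight and its inverse

The fraction of posterior precision contributed by the source data,

    w = [1/(sigma0^2 + sigma_delta^2)] / P,

is the quantity communicated to clinicians ("how much weight should the
older children's data get?"). It decreases strictly in `sigma_delta`, with
maximum `w_max = sigma1^2/(sigma0^2 + sigma1^2)` at full pooling.
`sigma_delta_from_weight` inverts the formula,
`sigma_delta = sqrt(sigma1^2 (1-w)/w - sigma0^2)`; weights above `w_max`
are rejected (no nonnegative `sigma_delta` can borrow that much). The
round trip `w -> sigma_delta -> w` is exact to 1e-10.

When a weight is converted to `sigma_delta` for the trial analysis, the
standard errors entering the formula are the *planning* values
`sqrt(4 p (1-p) / n)` at the final subgroup sizes (707 and 85) and the
assumed common failure rate p = 0.18. This convention reproduces the
borrowed effective sample size of 301 children for the elicited weight of
0.78 (85 * 0.78/0.22 = 301.4), which is the consistency anchor for all
planning numbers in the package.

### Effective sample size

`effective_sample_size` converts the down-weighted source variance
`sigma0^2 + sigma_delta^2` back into the number of target-population
children with the same information content, `4 p (1-p) / (sigma0^2 +
sigma_delta^2)` at 1:1 allocation, rounded to the nearest integer (halves
away from zero, as everywhere in the package).

## Elicitation analysis

Experts state an uncertainty range `(a, b)` for the target-subgroup risk
difference and the probability `p` they assign to it, conditioning on the
source effect being known exactly (a hypothetical "very large trial"). The
range is treated as a central, equal-tailed interval of a normal
distribution:

    mu = (a + b)/2,    sigma = (b - a) / (2 * Phi^{-1}((p+1)/2))

so the fitted normal assigns probability exactly `p` to `(a, b)` — the
self-consistency the tests assert. Because the conditioning removes all
sampling uncertainty about the source effect, the fitted `sigma` *is* that
expert's `sigma_delta`, and converts to a weight through the planning
standard errors (`opinion_to_weight`). Panel weights are pooled by the
median — a "typical expert" summary that extreme opinions cannot drag —
with quartiles by linear interpolation between order statistics (the rule
is echoed in CLI output since other interpolation conventions exist).

The pre-specified consensus rule asks whether some 30-percentage-point
window contains at least 80% of the experts' weights. We implement the
windowed reading (scan closed windows anchored at each sorted weight)
rather than "overall range <= 30 points"; when every expert is inside one
window the two readings agree. The window/fraction are parameters, so the
stricter reading is available by checking `best_window` coverage of the
whole panel.

Stage-2 responses (conditioning on a zero source effect) are fitted and
reported but do not set `sigma_delta`; the analysis uses stage-3 chosen
weights, with an expert's stage-1 range mapped to a weight as the fallback
when they prefer their range to stand.

## Power evaluation

`simulate_trial` realises the planning assumptions: within each subgroup,
participants are split 1:1 between arms (fixed split, DTG receives the
floor); each participant independently drops out with probability `ltfu`
(complete-case analysis); failures are binomial at the arm's true rate.
The risk difference is the difference in observed failure proportions,
with a Wald standard error; an arm with a zero cell has 0.5 added to both
its cells (only that arm) to keep the standard error finite. A trial with
an empty analysed arm is redrawn — at the default sizes this is a
never-event, but the guard keeps small designs safe.

`predictive_power` holds `sigma_delta` fixed at its elicitation-derived
value across replicates (the realised weight varies with each trial's
estimated standard errors, as the posterior formula implies) and counts
trials whose 95% credible upper bound falls below the margin.
`standalone_power` applies the frequentist rule `estimate + z * se <
margin` to the target subgroup alone. Both default to 20,000 replicates
(Monte-Carlo standard error about 0.3 percentage points at power 0.8) and
report their seed.

Two closed-form cross-checks accompany the simulators.
`analytic_standalone_power` is `Phi((margin - d)/se_plan - z)` with the
planning standard error at the LTFU-deflated target size;
`analytic_predictive_power` is the delta-method analogue treating both
subgroup estimates as normal with their LTFU-deflated planning variances.

### Known finite-sample behaviour

The binomial simulation sits systematically *above* the normal
approximation for the standalone analysis at the default size: exact
enumeration over all outcome tables gives 22.1% against the
approximation's 20.6% (18% failure, 10% dropout, 10% margin). This is
Wald-interval small-sample behaviour — the estimated standard error
shrinks exactly in the samples with few failures, which are the samples
near the declaration boundary — plus lattice effects; alternatives such as
an add-one-per-cell standard error move the exact value only to 21.5%. For
the same reason the type-I error of the standalone rule with the true
effect at the margin measures 2.7% rather than the nominal 2.5%. The
simulators report what the analysis would actually deliver; the analytic
formulas describe the large-sample limit, and the unit tests compare the
two at tolerances that acknowledge the gap. The delta-method cross-check
of the borrowing analysis agrees with its simulator to well within
Monte-Carlo error, because the posterior there is dominated by the much
larger source subgroup.

Under the planning conditions (707/85 children, 18% failure in every arm,
10% dropout, elicited weight 0.78) the predictive power of the borrowing
analysis computes to about 76% at 20,000 replicates, against roughly 20%
for the standalone analysis of the 85 children alone — close to a
four-fold gain from borrowing. Published planning work for this design
quotes a somewhat higher predictive power; the simulation behind that
figure is not specified to the level needed to reproduce it exactly
(dropout mechanics, per-replicate standard-error estimation, and the exact
posterior computation all matter at the level of a few points), so this
package reports what its own documented simulator computes rather than
calibrating to the quoted figure.

## Synthetic data

The fixture module regenerates every scenario from printed constants: the
planning design (707/85, p = 0.18, 10% LTFU, 10% margin, weight 0.78) and
the two worked examples (source −2%, CI −8% to 4%; target +7%, CI −10% to
24%, or −10%, CI −25% to 5%), with standard errors reconstructed from the
confidence intervals under the symmetric-normal assumption.
`generate_participants` produces participant-level tables matching the
simulator's distributional assumptions (it uses per-participant Bernoulli
draws, so its summaries agree with `simulate_trial` in distribution, not
bit-for-bit). `generate_elicitation_panel` builds a synthetic expert panel
by drawing intended weights around a centre, back-deriving each expert's
`sigma_delta`, and emitting the corresponding stage-1 ranges and stage-3
weights; pooling the panel recovers the generating centre within
Monte-Carlo tolerance. The synthetic panel is symmetric-normal by
construction — real experts are not — and it shares one coverage
probability across experts, so it exercises the pipeline's arithmetic, not
the behavioural variety of a real elicitation.

What passing tests show, and what they do not: the package reproduces the
closed-form planning arithmetic exactly and its simulators are internally
consistent and cross-checked; none of this validates the normal
approximation for a *real* trial's data (where failure counts may be small
and risk differences near boundaries), nor the elicitation protocol
itself.

## Numerical conventions

- Proportions internally, percent only at I/O boundaries.
- `z` is the exact 0.975 normal quantile (1.959964...), never 1.96.
- Display rounding is to the nearest integer percent, halves away from
  zero; machine output is unrounded.
- A standard error of zero is rejected as outside the model rather than
  treated as infinite precision.
- Weight-to-`sigma_delta` inversion clamps float round-off at the pooling
  bound to zero (tolerance 1e-14 relative to the target variance).

## Limitations

- Two subgroups only; no hierarchical shrinkage across many subgroups and
  no adaptive/mixture commensurate priors.
- Risk differences with normal approximation only; no survival endpoints,
  odds ratios, or exact-binomial posteriors.
- Standard errors are conditioned on, so very small subgroups (a handful
  of events) are outside the model's comfort zone.
- The consensus and pooling rules are the pre-specified ones; no
  behavioural (Delphi-style) aggregation is attempted.
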