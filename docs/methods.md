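# Methods

This note documents the models, the estimation and inference machinery, the
synthetic-data generator, and the numerical and design choices behind them.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task and identifiability

The task crosses five win probabilities {.10, .25, .50, .75, .90} with seven
amounts {$5, $10, $20, $30, $40, $50, $100} against a certain $5 — 35 trials
per condition, order seeded-random, screen side counterbalanced 18/17 (an odd
trial count cannot split evenly). Money is held internally as integer cents
and probabilities as integer percent, so expected values and earnings sums
are exact: the ceiling of the standard set (sum of highest-EV choices) is
exactly $662.50.

Under power utility the risky and safe options cross at
α\* = ln(1/p)/ln(v/5), defined when v > $5 (the $5-amount gambles are
dominated and never preferred). The largest crossing in the grid is
ln(10)/ln(2) ≈ 3.32, from the 10%-of-$10 lottery: noise-free choice vectors
are constant above it, and between 2 and 3.32 they change by a single trial.
This bound is the declared meaning of "recoverable" here, and it motivates
the exclusion thresholds below.

## Choice models and likelihood

All models share the logistic rule P(risky) = 1/(1 + exp(β ΔEU)) with
ΔEU = EU_safe − EU_risky. Log-probabilities are computed as
−log(1 + e^x) via `logaddexp`, never by exponentiating β ΔEU directly:
with $100 amounts and α near 2 the argument can exceed 10⁴ and the naive
form overflows. Utilities are computed on raw dollar amounts (no
normalization); β absorbs the units.

In the Opposite context "chose risky" means the risky option was assigned to
*self*; the friend implicitly receives the other option. The social model's
assignment utilities are therefore

    EU(risky→self) = (1−w)·p·v^α + w·5^α_f
    EU(safe→self)  = (1−w)·5^α + w·p·v^α_f

with α_f the participant's believed friend exponent, estimated once from
their predicted-friend block and then held fixed. With w = 0 the social model
reduces to the original model exactly (a nesting identity the tests assert to
machine precision).

The prospect-theory comparison model uses Tversky–Kahneman weighting
π(p) = p^γ / (p^γ + (1−p)^γ)^{1/γ} on gains only — the task has no losses —
with γ ∈ (0, 1.5]. It exists for AIC comparison harnesses, not for inference.

## Estimation

Fits are per participant × condition (never hierarchical, so no age structure
is imposed before the age-trend stage), by bounded L-BFGS-B from a multi-start
grid (α ∈ {0.2, 0.55, 1.0, 1.8} × β ∈ {0.5, 2, 8} × w ∈ {0.1, 0.35, 0.7}
where applicable) over the boxes α ∈ [0.01, 5], β ∈ [0.001, 50], w ∈ [0, 1].
Two estimation details matter:

* **Weight ridge and tie-breaking.** Whenever a participant's own exponent is
  close to their believed friend exponent, the likelihood is exactly flat
  along a (w, β) ridge — the data identify only β(1−2w) — and more generally
  w is identified solely through the curvature difference between α and α_f.
  Multi-start solutions then tie to within numerical noise, and a global
  arg-max lands on the w = 0 boundary for a large share of fits, which is a
  degenerate report rather than evidence. Among starts whose log-likelihoods
  tie within 0.01, the fitter therefore prefers solutions interior in w; a
  boundary solution that beats every interior one by more than that is kept.
  Tie-breaking applies to w only: extending it to all parameters measurably
  biased the exponent.
* **Restricted exponent range for the social model where appropriate.** The
  recovery harness refits with α ≤ 2, the range in which the social model is
  identifiable (above it, deterministic behaviour stops changing and α trades
  off against w along a second ridge). Study fits use the full box and rely
  on the exclusion rules instead.

AIC is 2k − 2·logLik with k = 2 (original), 3 (social, α_f not counted — it
is fixed, not estimated jointly), 3 (prospect theory). The chance comparator
uses the *same* k as the fitted model: AIC comparisons are only meaningful on
a common penalty convention, and the chance model is the fitted model at
β = 0.

### Exclusions

Per condition (not participant-wide; a config toggle reproduces full-sample
sensitivity analyses): Baseline/Identical-family fits with α̂ > 3.32;
Opposite-family fits with α̂ > 2 or ŵ < 10⁻⁶; any fit with AIC ≥ chance AIC.
On the default synthetic cohort the overall exclusion rate is below 10%,
dominated by Opposite-family weight degeneracies.

## Age-trend inference

The model is dv ~ condition + f_condition(age) + (1|dyad) +
(1|participant:dyad):

* cubic B-spline bases, dimension 10, knots at quantiles of the observed
  ages, second-order difference penalties; one smooth per condition level
  (its own smoothing parameter), each centred (sum-to-zero over its active
  rows) so the parametric condition terms carry the level differences;
* random intercepts as ridge-penalized dummy blocks, their variances selected
  together with the smoothing parameters; the participant block is included
  only when participants contribute more than one row;
* Gaussian smoothing parameters by restricted maximum likelihood (REML),
  optimized over log-λ by Nelder–Mead on the profiled criterion
  (n−M)·log P + log|H| − log|S_λ|₊. The fit agrees with an independent
  penalized-spline REML implementation (R `mgcv`) on the same data to well
  within the residual noise (cross-checked in the tests);
* coefficient uncertainty is the Bayesian posterior covariance σ̂²H⁻¹; the
  effective degrees of freedom are tr(H⁻¹XᵀX), reported per term.

**Simultaneous bands.** Derivatives use central finite differences with step
10⁻⁴ × age range (stable for cubic splines), evaluated at 100 ages spanning
the observed range. A draw-based critical value — 10,000 coefficient vectors
from N(β̂, V), the 95th percentile of the maximum standardized absolute
deviation over the grid — widens the pointwise intervals into a band with
~95% joint coverage. Significant windows are the maximal runs of grid points
whose band excludes zero. The same machinery produces between-condition
difference bands (including the parametric offsets, so they are full
population-level contrasts). On null cohorts with no age trend the windows'
type-I error is at or below 7.5% per dataset (computed in the tests), and the
bands are validated against a parametric-bootstrap oracle on a small fixture.

**Proportions.** Earnings proportions use a Beta family with logit link.
Smoothing parameters come from the Gaussian REML fit to the logit-squeezed
response; the Beta fit itself is penalized maximum likelihood at those λ
(Fisher scoring in the coefficients alternating with a bounded 1-D search in
the precision φ), with covariance from the penalized information matrix and
z statistics for parametric terms. Proportions at the boundary are squeezed
by (y(n−1)+0.5)/n — the Beta family excludes 0 and 1 — and the squeeze is
recorded on the returned fit. Selecting λ on the working logit scale rather
than by full Beta REML is an approximation; for these well-filled designs the
selected smooths are insensitive to it.

The pipeline's four analyses follow the study's questions: baseline age trend
(derivative windows for α̂ and earnings proportion); Identical and Opposite vs
Baseline difference bands (the two social contexts are never contrasted with
each other — they differ in cognitive demands); observation contrasts within
context via a 4-level condition factor, never a 2×2 interaction; and the
friend-weight age trend in the Opposite condition.

## Synthetic cohort

The generator defines the testbed conditions: 64 dyads (128 participants),
ages uniform on 12.0–22.8 with partners within 1.39 years; true α ~
Normal(0.55, 0.23) truncated to (0.05, 2); β ~ LogNormal(ln 3, 0.5) (this
noise level reproduces an earnings proportion near 0.92 of the ceiling, the
level a well-calibrated sample attains); belief about the friend's exponent =
friend's true α + Normal(0, 0.1), truncated; true friend weight
w = clamp(0.80 − 0.025·age + Normal(0, 0.12), 0, 1) — a linear decline with
mean ≈ 0.36 at the sample's mean age; condition shifts on α of +0.04
(Identical family) and an additional +0.10 under observation in the Identical
context; and an Opposite-context shift of +0.35 at age 12 declining linearly
to zero by age 19. The taper's cohort average (≈ +0.11) produces the
context's overall mean effect, while only its early-adolescent portion is
large enough to clear a simultaneous band, so the detectable window is
confined to the youngest ages — a shift tapering to zero by mid-adolescence
would average out to nearly nothing and reproduce no overall effect at all.

What the generator does *not* emulate: real heterogeneity beyond these
parametric forms (bimodal weights, lapses, side biases, trial-order effects),
observation effects on the friend weight (none are injected), or loss-domain
choices (the task has none). Passing tests therefore show that the pipeline
recovers structure *of this kind* at study scale — not that the published
estimates are correct.

## Parameter recovery

The recovery harness draws α ~ U(0, 2), w ~ U(0.05, 0.95), holds β = 3
(a typical estimated noise level) and draws α_f from the realistic belief
distribution N(0.55, 0.25) truncated to (0.05, 2), simulates one 35-trial
Opposite block per agent, refits with α restricted to [0, 2], and correlates
truth with estimates. Two intrinsic limits shape the attainable quality:
w and β are confounded when α ≈ α_f, and strong between-agent β heterogeneity
leaks into ŵ; a brute-force grid search over the full parameter box attains
essentially the same correlations as the multi-start fitter, so the reported
values sit at the estimator's information limit rather than at an optimizer
artifact. At mid-range true weights (w ≈ 0.5) the mixture nearly cancels and
ŵ scatters widely with a mild pull toward the w = 0 ridge; recovery there is
bounded, not unbiased.

## Known limitations

* The friend weight is weakly identified for participants whose own exponent
  matches their believed friend exponent; no estimator can fix this — it is a
  property of the design (35 binary trials) and the model family.
* Derivative and difference windows are implementation-sensitive at their
  endpoints; they should be read as qualitative age regions.
* The Beta-family smoothing-parameter selection is two-stage, not full REML.
* Problem sizes in the test suite (cohort of 64 dyads, 200 recovery agents,
  200 null replicates at 2,000 band draws) are the package's default desk
  scale; all are configurable upward.
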