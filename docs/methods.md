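# Methods

## The scoring engine

The GUS instrument scores one inhaler at a time through five boxes whose
sub-scores sum to a 0–50 total: (1) preference at glance after a
standardized nurse demonstration; (2–4) nurse-measured actuation
performance — critical issues noticed, attempts until a correct actuation,
seconds until autonomous handling; (5) ten closed acceptance/preference
questions. The published instrument's item weights are not public, so the
engine is configuration-driven: a scheme (JSON) declares, per box, item
rules that are either categorical option→points maps or monotone
non-increasing threshold maps over half-open intervals `[lo, hi)` (a value
on a boundary scores with the interval it opens; this makes boundary
behaviour unambiguous). Validation enforces the structural constraints any
valid scheme must satisfy: exactly five boxes, box maxima summing to 50,
non-negative awards, threshold rules monotone and partitioning their
domain. The shipped default scheme (box maxima 10+10+10+10+10, one
measurement item per nurse box, ten one-point closed questions) is a
clearly-labelled placeholder honouring those constraints — **not** the
published weights — and real studies should supply their own scheme file.
Missing answers raise errors rather than being imputed, because the
instrument is administered under nurse supervision and a blank is a data
error.

## The indirect-comparison model

Within one experience stratum (DPI-experienced and DPI-naive cohorts are
always analysed separately), respondent *i*'s score on device *k* is

    y_ik = mu_i + delta_ik + eps_ik,  eps_ik ~ N(0, tau^2),

with `delta` zero at the respondent's baseline device b(i) (first of their
tested set in canonical alphabetical order; Breezhaler under the study
design, which also makes it the natural reference because it is the only
device tested by all three groups). FE: `delta_ik = d_k − d_b(i)`. RE: the
p-vector of a respondent's contrasts is MVN with means `d_k − d_b(i)`,
variance `sigma^2`, covariance `sigma^2/2` — the standard construction that
keeps multi-arm contrast sets internally consistent. Respondents are the
exchangeable units; respondent intercepts `mu_i` get a vague normal prior,
which subsumes both the "groups as studies" and the "individuals as
studies" readings of an indirect-comparison setup.

Default priors, all vague on a 0–50 bounded outcome: `d_k ~ N(0, 100^2)`,
`mu_i ~ N(25, 100^2)`, `tau ~ U(0, 50)`, `sigma ~ U(0, 25)`. Respondents
contributing a single device are excluded from fitting (they carry no
within-respondent contrast) but retained in summaries, with a logged
warning. Fitting requires the stratum's evidence network to be connected;
a disconnected network raises before any sampling.

### A structural identifiability fact that shaped the implementation

With exactly one score per respondent–device cell, the within-respondent
contrast `w_ik = y_ik − y_ib` has variance `sigma^2 + 2 tau^2` and, for two
contrasts sharing the baseline, covariance `sigma^2/2 + tau^2` — exactly
half the variance *whatever the split between sigma and tau*. All
likelihood information about the two variance components therefore enters
through the single combination `sigma^2 + 2 tau^2`; sigma and tau are not
separately identified (there are no replicates within a cell to separate
measurement noise from preference heterogeneity). Two consequences:

* **Sampler.** A naive Gibbs sampler that conditions on the latent
  contrasts (or on `mu`) pins the pair to a point on this ridge and mixes
  very poorly across it. The implemented sampler is collapsed: the
  contrasts are integrated out analytically everywhere, `mu` and `d` use
  exact conjugate updates under the contrast-marginal likelihood, and
  `(tau, sigma)` moves by adaptive random-walk Metropolis (log scale,
  adaptation during burn-in only) against the likelihood with *both* the
  contrasts and `mu` integrated out — a partially collapsed step that is
  valid because `mu` is redrawn from its exact full conditional immediately
  afterwards. All covariance algebra uses closed forms (the contrast
  covariance is `aI + bJ`; integrating `mu` is a rank-one update), so no
  factorizations are needed in the hot loop. Per-iteration contrast draws
  are reconstructed from their exact conditional for export.
* **What an RE fit can and cannot show.** On heterogeneity-free data the
  posterior of sigma does not collapse to zero — the data cannot
  distinguish preference heterogeneity from residual noise here. What the
  model does recover is the identified combination: the RE posterior of
  `sigma^2 + 2 tau^2` matches the FE fit's `2 tau^2` and the simulation
  truth, which is the property the test suite asserts.

### DIC and model choice

DIC = Dbar + pD with pD = Dbar − D(posterior means). The deviance focus is
the population level for both models: `−2 log p(y | d, tau, sigma)` with
`mu` and the contrasts integrated out, so the FE deviance is exactly the
`sigma = 0` special case of the RE one and the two DICs compare like for
like. (Conditioning on the latent contrasts instead lets the RE model
absorb residual noise into them and makes it win arbitrarily — an artifact
of focus, not of fit.) The plug-in point uses posterior means on the
*variance* scale (`tau^2`, `sigma^2`): the likelihood is parameterized by
variances, and on the identifiability ridge this keeps the plug-in inside
the posterior's high-density set, where means of (tau, sigma) themselves
would not be. Under this focus pD lands at the effective parameter count
(≈ 7 for FE: six free device effects plus tau) and FE vs RE DICs on
heterogeneity-free data differ by well under one point — the same
qualitative near-tie the published analysis reports — so the "RE only at a
≥ 3-point advantage" rule selects FE. Model selection: RE if and only if
`DIC_RE ≤ DIC_FE − 3`; ties and small differences go to the simpler model.

### Summaries, ranks, diagnostics

Absolute GUS levels are anchored per iteration: `G_k = Abar + d_k` with
`Abar` the iteration's mean respondent intercept (the published absolute
scale construction is unstated; this choice reduces to the cohort mean
under a flat profile). Device summaries report the posterior mean and the
central 95% credibility interval of `G_k`, sorted by mean. Rank
probabilities rank devices by `G_k` within each iteration (rank 1 =
highest GUS), breaking exact ties by canonical device order so the matrix
is deterministic; entry (k, r) is the fraction of iterations with device k
at rank r, making every row and column sum to one exactly. Convergence is
assessed with split-chain R-hat (threshold 1.05) and a Geyer
initial-positive-sequence effective sample size per scalar parameter; a
non-converged fit carries a warning flag, never a silent result.

Default sampling: 2 chains × 100,000 iterations with 20,000 burn-in, as in
the published analysis scale. The analysis scripts run at 2 × 12,000
(2,000 burn-in) and the statistical acceptance tests at 2 × 20,000 (4,000
burn-in); at these sizes all R-hats sit at or below ≈ 1.02 and the
Monte-Carlo error on posterior means of device effects is below 0.05 GUS
points, which is negligible against posterior spreads of ≈ 1–1.5 points.

## Cohort statistics

Two-proportion comparisons use the Wald interval with continuity
correction, `delta ± [1.96·sqrt(p1 q1/n1 + p2 q2/n2) + (1/n1 + 1/n2)/2]`,
clipped to ±100 percentage points — the only standard interval that
reproduces the published MDI-experience interval (19.6–58.2) from the
printed proportions; the attached two-sided p-value is the Yates-corrected
chi-squared test (which reproduces the printed p = 0.0007, where the
uncorrected Pearson test gives 0.0003). The standalone `chi_square_test`
is the uncorrected Pearson statistic with df = (r−1)(c−1). One-way ANOVA
is reconstructed from group summary statistics (between-group SS from
means and sizes, within-group SS from SDs) and is algebraically identical
to classic ANOVA on raw data. Inputs may be printed rounded percentages or
raw counts; counts are preferred. The SMI comparison is reported as the
delta only: no integer counts are consistent with the printed percentages,
so its interval is not reconstructible.

## The synthetic cohort generator

`paper_design()` fixes the study layout: groups 1–3 test
{Breezhaler, Spiromax, Nexthaler, Ellipta}, {Breezhaler, Spiromax, Diskus,
Turbohaler} and {Breezhaler, Genuair}, with 27/28/19 experienced and
9/9/11 naive respondents (totals 74 + 29 = 103). Scores are generated from
the same additive model the fitter assumes,
`y = clamp(round(mu_i + e_k + eta_ik + eps_ik), 0, 50)`, with anchor 25
(mid-scale, keeping truncation negligible for |e_k| ≤ 15; observed
truncation rates are logged), respondent SD 5, residual SD 5,
heterogeneity 0 by default (fixed-effect truth), and integer rounding
(questionnaire sub-scores are integer point awards). All latent draws are
returned as ground truth. The generator emulates the design and the
error structure, not real response behaviour: it has no item-level
dependence, no covariates (age, smoking, disease severity are descriptive
only), no learning or fatigue across the session, and Gaussian noise where
real box scores are discrete and bounded. Passing tests therefore
demonstrate correctness of the machinery and calibration under the assumed
model, not robustness to behavioural artifacts of real questionnaires.

`inverse_questionnaire` maps any achievable GUS total back to concrete
item answers by dynamic programming over box and item point sets
(uniformly randomized among valid choices given a seed), which gives the
end-to-end round-trip test `score(inverse(t)) = t` for every achievable
total; unreachable totals fall back to the nearest achievable value with a
warning.

## Numerical choices and degenerate inputs

Residual precision is drawn from its truncated-Gamma conditional (uniform
prior on tau); a zero residual sum of squares is floored at 1e-12, so
perfectly constant data drive tau to its lower bound instead of a division
error. Metropolis steps clip sigma to (1e-4, upper) and tau to (1e-3,
upper). The seed splits into per-chain streams via `SeedSequence`;
identical seeds give bit-identical draws, and record order never affects
results (respondents and devices are canonically sorted during
preparation). Rank ties (exactly equal `G_k`) resolve to canonical device
order via a stable sort.

## Known limitations

* sigma and tau are only jointly identified (see above); posterior
  statements about sigma alone mostly reflect the prior.
* The default scoring scheme is a stand-in; analyses of real GUS data must
  load the actual instrument weights.
* DIC values depend on the declared likelihood focus; the package's
  population-level focus is the right one for FE-vs-RE comparison but its
  absolute deviance values are not comparable to implementations that
  condition on latent effects.
* The naive stratum (n = 29) gives wide intervals and unstable rankings —
  visible in the analysis scripts exactly as in the published cohort.
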