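# Methods

## Model

The core model is a finite mixture over a latent categorical variable
`X` (the true p53 codon 72 genotype; `C = 3` classes) with prevalence
vector `π` on the simplex.  Each of `T` laboratory tests reports a
category with class-conditional classification probabilities
`θ_t[r|c] = P(test t calls r | X = c)`; each `θ_t` column is a simplex
vector, generalizing sensitivity and specificity to three categories.
Given `X`, tests are conditionally independent, so a subject with calls
`r_1..r_T` has marginal likelihood `Σ_c π_c Π_t θ_t[r_t|c]`.  Missing
calls are skipped in the product, which is the maximum-likelihood
treatment under MCAR missingness; a fully missing subject contributes
likelihood 1.  With `T ≥ 3` tests the parameters are identified without
any reference standard (Hui–Walter); the constraint is enforced when
building an unconstrained model specification.

The outcome-augmented model multiplies a Bernoulli factor
`ρ_c^{[d=2]} (1−ρ_c)^{[d=1]}` into each class term, where `d` is the
binary cytology outcome (1 = negative, 2 = SIL within two years) and
`ρ_c` the per-class cumulative risk.  Test accuracy is assumed
independent of the outcome; that assumption is itself testable with the
stratified-accuracy variant.  Odds ratios against a reference class
(default Pro/Pro) are `OR_c = odds(ρ_c)/odds(ρ_ref)` with delta-method
standard errors using the joint covariance of the risks.  Confidence
intervals are symmetric on the OR scale by default — matching the
published presentation convention — with a log-scale Wald interval as
an option.  A symmetric interval can cross zero for imprecise ORs; the
log-scale option avoids that.

## Estimation

Maximum likelihood by EM on the grouped representation: subjects are
collapsed to distinct response patterns (≤ `C^T` plus missing
variants), which is exactly equivalent to subject-level fitting and
makes every E/M step a small dense array operation.  The E-step
computes posterior class memberships per pattern; the M-step
re-estimates `π`, the `θ_t` columns, and `ρ` as posterior-weighted
proportions (closed form).  The equal-accuracy constraint pools the
M-step counts across tests.

Multimodality is the known failure mode, so each fit runs one
moment-style start (near-diagonal `θ`, prevalence set to the average
observed marginal call distribution — this anchors the intended
labelling) plus `n_restarts` Dirichlet random starts, keeping the best
local maximum.  Defaults: 20 restarts, relative log-likelihood
tolerance 1e-8, 5000 iterations, master seed 20130218; replicated
simulation studies use 2 restarts, which in pilot runs always found the
same optimum for the well-separated truths they simulate.  The
log-likelihood is asserted non-decreasing at every EM iteration; a
decrease raises immediately.  After fitting, latent class labels are
aligned by the permutation maximizing total diagonal classification
mass `Σ_t Σ_c θ_t[c|c]` (ties broken by descending prevalence), so
class `c` is reported as genotype `c`.

Probabilities may legitimately converge to 0 (boundary solutions).
Internally they are floored at 1e-12 for log-safety; on output,
parameters within 1e-6 of 0 are reported as exactly 0 with standard
error 0 and a boundary flag.

### Standard errors

SEs come from the numerically differentiated observed information on a
minimal parameterization: every simplex block (prevalence, each `θ`
column, each risk) drops its *largest* interior entry, boundary entries
are held fixed, and finite-difference steps shrink near 0/1 so the
likelihood is never evaluated outside the simplex.  Dropping the
largest entry (rather than always the last) matters: when a column's
remaining mass is concentrated near an edge, differencing across that
edge produces an indefinite Hessian.  The removed entry's variance is
recovered by the delta method as the summed covariance of its block.  A
rank-deficient information matrix triggers a warning and pseudo-inverse
SEs.  Profile-likelihood intervals are out of scope.

### Identifiability / degrees of freedom

Before fitting, the free-parameter count — `(C−1) + T·C·(C−1)`
unconstrained, `(C−1) + C·(C−1)` under equal accuracy, plus `C` risks
or the dependence terms where applicable — is compared with the number
of *distinct observed* response patterns minus one (the likelihood
depends on the data only through those counts, so this is a necessary
condition for a non-ridge maximum).  A fit that fails the check is
flagged unidentified and reported `converged = False` even if the EM
tolerance was met: the model cannot claim a meaningful optimum.  This
is what the outcome-stratified accuracy model does on a small stratum —
doubling the `θ` count against a handful of SIL cases — mirroring the
convergence failure such models show in practice.  Only this counting
check is performed; no algebraic identifiability analysis.

## Conditional dependence

For a flagged test pair, the within-class joint cell table is the
product form times `exp(λ · 1[r_a = r_b])`, renormalized — one
log-linear agreement parameter per pair, shared across classes by
default (per-class optional).  A test may appear in at most one pair;
the factorization is ill-defined otherwise.  `λ = 0` recovers the
conditional-independence model exactly.  The dependent model is fitted
by L-BFGS in an unconstrained additive-log-ratio parameterization,
warm-started at the EM independence solution with `λ = 0`, so its
log-likelihood can never fall below the independence fit.  `SE(λ)`
comes from the numerical Hessian in that unconstrained space.  The
dependence screen fits each of the `T(T−1)/2` pairs one at a time and
Bonferroni-adjusts the LRT p-values.

Likelihood ratio tests report `2·(ℓ_alt − ℓ_null)` against a chi-square
with df equal to the free-parameter difference; a null likelihood
exceeding the alternative's beyond tolerance raises (optimizer
failure), and fits with boundary parameters carry a warning that the
chi-square reference is then only approximate.

## Synthetic data generator

The generator inverts the likelihood into a sampler: per subject, draw
`X ~ Cat(π)`, the outcome `~ Bernoulli(ρ_X)`, each test call
`~ Cat(θ_t[·|X])` — or jointly from the renormalized pair table when a
dependence term is configured, so recovery tests and the fitter share
one parameterization — then apply per-test MCAR masking.  True classes
are returned separately for scoring.

Defaults are the study's conditions: n = 911 subjects; `θ` set to the
published classification-probability matrices (the published Arg/Arg
column of DBH sums to 1.023 as printed; its first entry is replaced by
the complement 0.974 of the other two, and columns off by 0.001 from
rounding are renormalized); `ρ = (0.090, 0.054, 0.050)`; missingness
1/911 on RFLP-2 and zero elsewhere.  True-genotype prevalences were
never published, so the default `π = (0.39, 0.44, 0.17)` was set once
to the panel's observed marginal call distribution; with the default
risks it implies ≈ 61 expected SIL cases in 911 women, the study's
case count.

What the generator does *not* emulate: visit schedules, HPV dynamics,
covariates (age, race), informative missingness, or any laboratory
error mechanism beyond a class-conditional confusion matrix with
optional pairwise agreement terms.  Passing recovery tests therefore
show the estimator is correct under the model's own assumptions — they
cannot validate those assumptions for real genotyping data.

## Reconstructed study panel

Only the six pairwise cross-tabulations of the four tests (stratified
by cytology) were published.  The packaged panel is *one* subject-level
dataset consistent with all of them, found by integer linear
programming over the 81 complete response patterns per stratum
(equality constraints on all 54 pairwise cells; objective: minimize
total pairwise disagreement, which makes the completion look like
plausible genotyping data), plus the single subject with a missing
RFLP-2 call, whose other calls the published missing margins pin to
Arg/Arg.  The reconstruction is frozen as a 530-byte grouped CSV and
verified cell-exact on load.  Anything that depends only on pairwise
margins (agreement, empirical prevalences and odds ratios) is exact;
latent-class fits involve higher-order structure the margins do not
determine, so fits on the panel describe the reconstruction — in
practice they land close to the published estimates, but the
dependence structure of the completion is an artifact of the objective
and supports no conclusions about the original data.

## Simulation studies: sizes and operating points

* Model-1 recovery: n = 5000 at the published `θ`; observed max error
  ≈ 0.02 on `θ` and ≤ 0.01 on `π` (tolerances 0.03 / 0.02).
* Outcome-model recovery: n = 20000; risks recovered within 0.015.
* LRT type-I calibration: 200 replicates at n = 2000, one shared-`λ`
  dependence term (df = 1).  The truth uses the published matrices
  smoothed with 2% uniform mass: several published entries are exactly
  0, and with a boundary truth the chi-square reference fails (the
  empirical null statistic distribution is visibly non-chi-square);
  an interior null is a precondition of the asymptotics being tested.
* Dependence power: `λ = 1` at n = 5000 with moderately accurate tests
  (diagonal 0.85).  Near-perfect tests agree within class regardless of
  `λ`, leaving the agreement term weakly identified; the moderate
  operating point is where power against real dependence is a
  meaningful property.  `λ̂` consistency was checked at n = 100000.
* Stratified-accuracy checks: equal-truth calibration at n = 4000 × 15
  replicates; stratum-difference recovery (one cell shifted by 0.15) at
  n = 8000 per stratum.

## Known limitations

* Conditional independence is the baseline assumption; a general
  pattern of positive error correlation would inflate accuracy
  estimates, and the pairwise terms probe but cannot exhaust such
  misspecification.
* Boundary solutions make SEs and chi-square references approximate;
  the two-category regrouping (Arg/Arg vs others, Pro/Pro vs others)
  is the supported mitigation.
* No covariate adjustment (latent-class regression) and no Bayesian
  estimation.
* The symmetric-on-OR confidence intervals reproduce the published
  convention but are not variance-stabilized; prefer the log-scale
  option for inference.
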