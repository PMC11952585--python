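# Methods

`smahp` implements a three-step mediation analysis for survival outcomes
with high-dimensional exposures (gene expression, `X`, n×p) and
high-dimensional mediators (protein abundance, `M`, n×k), adjusting for a
small set of clinical covariates (`Z`, n×q). The goal is to identify
(gene, protein) pairs for which the protein transmits part of the gene's
effect onto survival time, with false-discovery-rate control over the
tested pairs.

## Models

The outcome follows an accelerated failure time (AFT) model on the
log-time scale,

    log T = β_X'X + β_Z'Z + β_M'M + b·ε,

with ε standard normal (`family="lognormal"`, log-normal survival times)
or standard minimum extreme value (`family="weibull"`). Right-censoring
is handled through the censored likelihood (density terms for events,
survival terms for censored observations). Each mediator follows a linear
model `M_k = α_Xk'X + α_Zk'Z + ξ_k`. The natural indirect effect of gene
j through protein s is estimated by the coefficient product
`α̂_js · β̂_Ms`; the natural direct effect of gene j is `β̂_Xj`. Positive
coefficients mean longer survival. Exposures are standardized to unit
variance before the final models (toggle `rescale_exposures`), so effects
are per standard deviation of expression.

## The three steps

1. **Penalized screening.** A penalized AFT of log-time on all mediators
   yields candidate mediators 𝒮₁, a penalized AFT on all exposures yields
   candidate direct genes 𝒯 (lasso by default; MCP and elastic net with
   mixing 0.5 available). Each candidate mediator is then regressed on
   all exposures with an MCP penalty, yielding per-mediator candidate
   genes 𝒥₁ₖ.
2. **Pair screening (SIS).** For each s ∈ 𝒮₁ an unpenalized AFT of
   log-time on (X_𝒯, M_s) gives β̂_Ms, and an OLS of M_s on X_𝒥₁ₛ gives
   α̂; the pairs with the largest products |α̂·β̂| are kept, at most
   ⌊d·n/ln n⌋ of them (d = 1 by default; ties broken by mediator then
   gene index). This produces 𝒮₂ and 𝒥₂ₛ, nested inside the Step-1 sets.
3. **Joint-significance testing.** One joint AFT of log-time on
   (X_𝒯, Z, M_𝒮₂) provides β̂ and Wald p-values per mediator; per-mediator
   OLS of M_s on (X_𝒥₂ₛ, Z) provides α̂ and p-values per gene. Each pair
   is tested with `P_max = max(P_α, P_β)` (conservative under the
   composite null), and Benjamini–Hochberg is applied with the family
   taken as the full u×r tested matrix — u the number of distinct genes
   in ∪𝒥₂ₛ, r = |𝒮₂| — in which pairs dropped by screening count toward
   the correction but can never be rejected. Discoveries are pairs with
   adjusted p ≤ q (default 0.05).

## Numerical approach

The penalized AFT is solved in the transformed coordinates
(θ = β/b, φ = 1/b), in which both censored likelihoods are concave
(Tobit form). This matters for two reasons. First, in the original
(β, log b) coordinates the censored likelihood is unbounded whenever the
events can be interpolated (k ≥ number of events): solvers fall into a
scale-collapse spike under heavy censoring. Second, the ℓ1 penalty on
θ = β/b is scale-relative, so shrinking residual scale does not silently
weaken the penalty; empirically this also removes the lasso's tendency to
drop members of groups of correlated true mediators. The path over 100
log-spaced λ values (down to 0.01·λ_max) is computed by proximal Newton:
a quadratic expansion of the likelihood at each iterate, solved by
penalized weighted coordinate descent with active-set sweeps, step
halving on the true objective, warm starts across λ, and an early stop
once the active set exceeds n/2 (saturated fits that no selector
chooses). Relative-objective tolerance is 1e-6; at λ = 0 the solution
matches the unpenalized maximum-likelihood fit to better than 1e-3.

Unpenalized AFT fits use the same Newton solve followed by a bounded
L-BFGS polish in (β, log b), with the scale floored at 1% of the
least-squares residual scale (the unbounded-likelihood guard at small
event counts). Wald standard errors come from the inverse observed
information (central-difference Hessian of the negative log-likelihood).
The mediator regressions use cyclic coordinate descent on the Gram
matrix with the firm (MCP), soft (lasso) or scaled-soft (elastic-net)
threshold; Gram matrices are shared across mediators.

## Tuning-parameter selection for the screens

The screening fits need a λ rule. k-fold cross-validation (`"min"` and
`"1se"` rules, 5 folds, stratified on the event indicator, ties toward
the larger λ) is provided, but the package default is the extended BIC
(γ = 1) evaluated on **unpenalized refits** of each support along the
path (`"ebic"`; plain `"bic"` is also available). Two observations drove
this choice, both visible in the simulation study:

* any mediator admitted by a data-driven screen has, by construction, a
  selection statistic above the admission threshold; since the same data
  are reused by the joint-significance test, liberally screened null
  mediators re-enter Step 3 with systematically small β p-values and
  produce false pairs in batches (one per parent gene). CV-min admits
  dozens of null mediators; EBIC(γ=1) requires roughly |z| > 4 and admits
  almost none, while the true mediators (|z| ≈ 10 at the default effect
  sizes) are unaffected.
* information criteria evaluated on the shrunk path fits still
  over-select under correlation, because a correlated null feature buys
  genuine likelihood by compensating the shrinkage of the true features;
  evaluating the criterion on the ML refit of each candidate support
  removes this artifact.

## Synthetic data generator

The generator emulates a proteogenomic survival study and is the test
bed for every downstream stage. Defaults: exposures i.i.d. N(0.4, 0.5²);
covariates Z₁ ~ N(0.12, 0.75²), Z₂ ~ Bernoulli(0.3); mediators in four
blocks of proportions 40/40/10/10% — the first two blocks are X-driven
(each block shares one random 10% subset of the exposures as parents,
effect 0.8 per parent; block 1 additionally loads on Z with effects
0.2/0.2, residual sd 0.5; block 2 has residual sd 0.3), block 3 loads on
Z only (0.2/0.3, sd 0.5), block 4 is pure noise (sd 0.3). Survival:
log T is a linear combination of 2 direct-effect genes (effect 0.8,
drawn outside the active parent sets), 4 outcome mediators (effect 4.0,
drawn from the X-driven blocks) and both covariates (effect 0.12), plus
N(0, 1) error. Censoring times are exponential with the rate calibrated
by Monte Carlo (10⁵ event times pooled over 20 re-drawn truth
structures, fixed internal seed, root-finding on the analytic censoring
probability) to hit the target proportion of 25/50/75% on average over
generator seeds. Block sizes use floor(k·proportion) for blocks 1–3 with
the remainder in block 4. Ground truth (the set of (parent gene,
outcome mediator) pairs) is returned for scoring power and FDR.

Because the two X-driven blocks share parent sets, mediators within a
block are strongly correlated (≈0.76 at p=50, ≈0.87 at p=100) — this is
what makes the p=100 scenarios genuinely hard for marginal screening and
separates the penalized pipeline from the SIS+SIS baseline. What the
generator does **not** emulate: correlated exposures, heavy-tailed or
misspecified AFT errors, informative censoring, measurement error, and
the block structure of real proteomes; passing tests therefore
demonstrate internal correctness and the claimed operating
characteristics under the stated generating process, not performance on
real proteogenomic data.

The AFT error sd (1.0) and the counts of outcome-associated genes (2)
and mediators (4) are generator defaults of this package; with 10%
parents per mediator they give 20 true pairs at p=50 and 40 at p=100,
which is what makes the ⌊n/ln n⌋ = 37 pair budget binding at n=200 in
the p=100 scenarios.

## Evaluation conventions

Power and FDR are defined at the (gene, mediator) pair level: power =
discovered true pairs / true pairs; FDR = false discoveries /
max(1, discoveries); both averaged over replicates with Monte-Carlo
standard errors reported. Replicate r of a study cell uses generator
seed `seed + r`; all methods see the same datasets. The study harness
(`run_study`) reports per-cell means, Monte-Carlo standard errors, and
mean runtimes (logged, never asserted).

The bundled comparators: `sis_sis` replaces Step 1 by univariate
marginal screens (top ⌊n/ln n⌋ mediators and exposures by AFT Wald
statistic, top ⌊n/ln n⌋ genes per mediator by OLS t-statistic) and then
runs Steps 2–3 unchanged; `naive` tests every one of the p·k pairs from
marginal models (per-mediator AFT with covariates, per-pair OLS with
covariates) with BH over all pairs.

Reported study sizes: the acceptance script and the acceptance tests use
50 replicates per cell (the simulation design uses 200 by default);
Monte-Carlo standard errors at 50 replicates are ≈0.01–0.04 for the
quantities checked, comfortably inside the ±0.10 bands used by the
checks.

## Degenerate inputs and edge rules

All-censored data are rejected (the scale is not identifiable). Constant
feature columns are rejected by the penalized fits and assigned p = 1 by
the univariate pre-screen. An empty 𝒮₁ or empty candidate-gene sets
short-circuit to an explicit "no candidate mediators" result. Exact
product ties in SIS break lexicographically; active sets use a 1e-8
threshold on standardized coefficients. Rank-deficient final designs
drop offending columns (with a warning); numerically singular observed
information triggers removal of the most collinear column and a refit.
Missing values are handled by complete-case analysis with the dropped
count reported.

## Known limitations

The max-p test is conservative under the complete null but inherits
selection bias when screening and testing reuse the same data; the
strict EBIC screen keeps this small at the study's effect sizes, but
residual FDR inflation remains at 75% censoring with n=200 (as in the
reference tables). The parametric likelihood screen is efficient when
the error family is correct (as in the generator); under misspecified
errors the `weibull`/`lognormal` choice matters and a rank-based screen
could be preferable. Competing risks, time-varying covariates and
pathway-level (grouped) mediation are out of scope.
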