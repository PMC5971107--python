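# Methods

## The estimand

For a cohort of N subjects with J scheduled visits, let `Y_j` be a
continuous outcome, `R_j` the response indicator (monotone missingness,
`R_1 = 1`), `D ∈ {1..J}` the last visit at which the subject is alive
(`D = J`: alive at study end), `Z` baseline analysis covariates and
`X ⊇ Z` fully observed auxiliary covariates.  Outcomes are undefined after
death; the package distinguishes *missing while alive* (`j ≤ D`, `R_j = 0`)
from *undefined post death* (`j > D`), and post-death cells never enter any
estimating equation or imputation model.

The target is the **partly conditional mean** — parameters β of the linear
model

    E(Y_j | Z, D ≥ j) = β' Z_j,

the mean among subjects still alive at visit j.  Unconditional ("immortal
cohort") means require implicit imputation of outcomes for the dead and are
not meaningful when mortality is non-negligible; fully conditional means
(`E(Y_j | Z, D)`) are also expressible through the design but are not the
default.  The default design (`visit_sex_design`) is the saturated
visit/sex specification: intercept, indicators for visits 1..J−1 (visit J
is the reference), a sex main effect, and visit×sex interactions.

## Estimators

All estimators solve a weighted independence estimating equation

    Σ_i Σ_j Z_ij I(D_i ≥ j) R_ij w_ij (Y_ij − β'Z_ij) = 0,

which with an identity link is linear in β and solved in closed form; the
default variance is a subject-clustered sandwich treating weights as fixed,
with a cluster bootstrap available for pipelines whose first-stage
uncertainty the sandwich ignores.

* **CC / IEE** — unit weights on complete cases / on all observed survivor
  cells.  Consistent only when dropout among survivors is independent of
  the outcomes given covariates.
* **IPW_u / IPW_p / IPW_f** — weights are inverse cumulative products of
  per-visit logistic dropout hazards `P(R_k=1 | R_{k−1}=1, history, X, ·)`.
  The variants condition the component models on survival to the current
  visit (u), to the target visit (p; one model per (k, j) pair, refitted
  for every target), or on the death time itself (f; stratified on D, with
  small strata — fewer than 30 at risk, or separated fits — falling back to
  a D-as-categorical-covariate model, or D-as-covariate throughout).  They
  are consistent under, respectively, u-MAR, p-MAR and f-MAR.  Fitted
  observation probabilities are floored at 0.01 before inversion (logged);
  the hazard history is the lag-1 outcome by default (matching the
  simulators), with a full-history option.
* **MI_u / MI_f** — monotone sequential multiple imputation.  Per-visit
  normal linear regressions of `Y_j` on the outcome history and X (plus D
  as a covariate, or chains per death stratum, for the f variant) are
  fitted on observed cells; each of M = 30 imputations draws (σ², coef)
  from the standard non-informative posterior (scaled inverse chi-square ×
  conditional normal) and fills missing-while-alive cells sequentially,
  feeding fills forward.  Imputed post-death outcomes are never produced;
  estimates are pooled by Rubin's rules (variance `W + (1+1/M)B`).  For
  monotone continuous data this sequential scheme is equivalent to joint
  multivariate-normal imputation.  Valid under mortal-cohort dDTIC +
  independent death (u) or f-MAR (f).
* **LI_u / LI_f** — the deterministic conditional-mean fill from the same
  per-visit regressions (the infinite-imputation limit of MI, in the
  spirit of the linear-increments method); variance via the cluster
  bootstrap.
* **AIPW_u / AIPW_f** — augmented IPW.  With `U(β) = Σ_{j≤D} Z_j(Y_j −
  β'Z_j)` and `H_j(β)` the same quantity evaluated on the record completed
  beyond visit j by recursive conditional-mean (Paik) predictions, a
  subject contributes

      (R_D/π̃_D) U(β) + Σ_{j<D} (R_j/π̃_j − R_{j+1}/π̃_{j+1}) H_j(β),

  where `π̃_j` is the cumulative product of logistic hazards in the lag
  history and X (plus D for the f variant).  `H_D = U` holds by
  construction (asserted at assembly), the system is linear in β (one-shot
  solve; the coefficient on the Gram matrix telescopes to 1), and the
  estimator is consistent if *either* nuisance model is correct (double
  robustness), and at least as efficient as the matching IPW when both
  are.  γ (Paik) and α (hazards) are estimated first and plugged in; the
  default sandwich ignores their variability, the bootstrap covers it.

## Synthetic-data generator

Three sequential mechanisms with a binary baseline covariate (sex,
P = 0.5) and a lag-1 linear-normal outcome chain (`Y_1 ~ N(5 − 0.5·sex,
1.2²)`, `Y_j = 1 + 0.7·Y_{j−1} − 0.35·sex + N(0,1)`, J = 5), differing in
what survival and dropout may depend on:

* **dag1** — survival and dropout at j are logistic in the *latent*
  `Y_{j−1}` and sex.  u-MAR holds; independent death fails.
* **dag2** — survival depends on the last *observed* outcome (carry-forward
  of the Y* history); dropout on `Y_{j−1}`.  Mortal-cohort dDTIC and
  independent death hold; missingness-independent death, u-, p- and f-MAR
  fail.
* **dfirst** — D is drawn first (logistic hazards in sex), then outcomes
  and dropout hazards both condition on D (linearly via `D − 3`, with
  stronger sex effects).  f-MAR holds *exactly* and the f-variant nuisance
  models are exactly correctly specified; u-MAR fails.

Hazard intercepts were calibrated once (bisection at N = 4·10⁵) so that at
the defaults ≈24% of the N·J outcome cells are lost to death and ≈27% of
alive cells are unobserved; the survival-outcome coupling (coefficient 1.0
on the lagged outcome, with a survival-intercept profile declining over
visits) was set so the mechanisms reproduce the qualitative regime the
methods are meant to separate — imputation ignoring death visibly biased
under dag1, weighting methods visibly biased under dag2 — while visit and
sex contrasts stay of order 0.1–1.  These constants are frozen defaults,
not tuning knobs.

What the generator does *not* emulate: continuous death times,
time-varying covariates, non-monotone missingness beyond the monotonising
pre-step, non-normal outcomes, and auxiliary covariates beyond those in Z.
Passing tests therefore demonstrate correctness of the estimators under
the stated identifying assumptions, not robustness to features of real
cohort data outside this model family.

**Truth oracle.**  True β are Monte-Carlo estimates: simulate ~10⁶ subjects
under the *unmodified* mechanism, reveal the latent outcomes of all alive
cells, and fit IEE (unbiased under full observation of survivors).  The
mechanism is left running rather than disabling dropout because under dag2
the survival process depends on the dropout process through the last
observed outcome; for dag1/dfirst the two constructions coincide in
distribution.

## Exact assumption checking

On a finite discrete joint law of (X, D, last-observed visit, Y_1..Y_D),
each identifying condition (u-/p-/f-MAR, mortal-cohort dDTIC, independent
death, missingness-independent death) is checked by enumerating every
instance of its defining conditional equality; the checker reports the
maximum absolute difference, with ≤ 1e-10 counting as "holds" and
zero-probability conditioning events skipped as vacuous.  Quantifier
ranges follow the definitions exactly (missingness-independent death is
quantified over j ≥ 3; for J ≤ 3 an all-j variant would add only
trivially satisfied instances, since `R̄_1` is constant).

Simulator configs with J ≤ 3 are bridged to exact checks by replacing each
normal draw N(μ, σ²) by the two-point law {μ−σ, μ+σ} (matched conditional
mean and variance); the logistic structure is evaluated exactly on the
resulting grid, so the mechanism's conditional-independence structure is
preserved.  One artifact: in the discretized dfirst mechanism a nonzero
outcome-on-D coefficient shifts the outcome grids of different death
strata onto disjoint support, making the u-MAR instances vacuously true;
the structural check of "f-MAR holds, u-MAR fails" therefore uses a config
with that coefficient zeroed (the D→dropout link, which is what breaks
u-MAR, is kept).

The two directions of the u-MAR equivalence (u-MAR ⟺ dDTIC +
missingness-independent death) are exercised over random laws built by
temporal factorization (death depending arbitrarily on past outcomes,
dropout on the observed history — the hypothesis side) and over
unconstrained Dirichlet-random laws.  Because exact satisfaction of one
MAR variant is a measure-zero event under random search, the two
"neither p-MAR nor f-MAR implies the other" counterexamples are
constructed analytically: one law where a dropout–outcome dependence
inside the D = 2 stratum cancels exactly when strata are pooled (p-MAR
holds, f-MAR fails), and one where dropout depends only on D while death
depends on Y_2 (f-MAR holds, p-MAR fails).

## Study harness and numerical choices

`run_study` generates replicate datasets (per-replicate seeds spawned from
one master `SeedSequence`), applies each method, and reports bias×100,
standardized bias (100·bias/empirical SD; |s-bias| ≈ 40 is the
conventional "practically significant" flag) and empirical SE×100.
Replicate-level failures (separation, singularity) are excluded with a
logged count.  The default profile is 1000 replicates; the test suite runs
an 800-replicate fast profile and the acceptance script 500 (Monte-Carlo
SE of an s-bias is ≈ 100/√n_reps), with truth oracles of 1–1.5·10⁶
subjects.

Numerical choices: estimating equations are solved by direct linear
algebra with a QR-with-pivoting rank check that names collinear columns;
logistic hazards use Newton-Raphson (statsmodels) with separation detected
via non-finite or exploding coefficients; a hazard component with no
non-events is an error for a direct fit but becomes the constant hazard 1
inside estimator pipelines (so that zero-dropout data reduce every method
to IEE exactly); observation probabilities are floored at 0.01 before
inversion; imputation regressions with residual variance ≤ ~1e-12 of the
outcome scale are rejected as degenerate; MI requires M ≥ 2; the
assumption checker treats conditioning events with mass ≤ 1e-14 as
vacuous.

## Known limitations

Identity link and independence working correlation only (the partly
conditional weighting/augmentation theory requires independence);
single-covariate default designs are deliberately simple; the AIPW
sandwich ignores first-step nuisance variability (use the bootstrap);
p-variant weights can be unstable in small samples (more component models,
smaller fitting sets); the u-MAR screen is a one-degree-per-level LR test
and inherits the usual power limits of N ≈ hundreds.
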