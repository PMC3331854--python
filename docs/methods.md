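# Methods

## Model and likelihood

penreml estimates the additive-genetic and residual covariance matrices
(Σ_G, Σ_E) among q traits from a balanced paternal half-sib design: s
unrelated sires, n progeny each, every trait recorded on every progeny,
an overall mean as the only fixed effect.  Records are multivariate
normal; a sire transmits half its breeding value, so the between-sire
variance is Σ_G/4 and the within-family variance Σ_W = Σ_E + ¾Σ_G.  The
data enter only through the between- and within-sire mean-square/
cross-product matrices M_B (s−1 df) and M_W (s(n−1) df), whose
expectations are Σ_B = Σ_W + (n/4)Σ_G and Σ_W.  The REML log-likelihood,
up to an additive constant, is

    logL = −½[(s−1)(log|Σ_B| + tr(Σ_B⁻¹M_B)) + s(n−1)(log|Σ_W| + tr(Σ_W⁻¹M_W))].

A record-level REML likelihood (full (snq)² covariance matrix, mean
profiled out) is kept as a test oracle; it differs from the expression
above by a parameter-free constant, which the test suite checks.

## Penalized estimation

Sampling spreads the eigenvalues of estimated covariance matrices: the
leading canonical eigenvalues λ_i of Σ_P⁻¹Σ_G (Σ_P = Σ_G + Σ_E) are biased
up, the smallest down.  Estimates are regularized by maximizing
logL_P = logL − ½ψ·P(θ), where ψ ≥ 0 weights one of ten penalties:

* `P_lambda` — Σ(λ_i − λ̄)², the likelihood form of 'bending'.
* `P_lambda_log` — the same variance on log λ_i; `P_lambda_log2` adds the
  log(1−λ_i) part, symmetrizing the treatment of Σ_G and Σ_E.
* `P_beta_fixed` — negative log beta(α, β) kernel (default α=β=2) on
  eigenvalues rescaled to the range [λ_q⁰, λ₁⁰] observed in the
  unpenalized fit (a deliberately inflated range estimate); rescaled
  values are clamped to [1e−6, 1−1e−6] so the kernel stays finite if the
  penalized path leaves the range.
* `P_beta_mom` — beta kernel with method-of-moments shapes estimated from
  the unpenalized eigenvalues, acting on λ directly; a constant z (default
  1) added to both shapes guarantees uni-modality.  If the observed spread
  exceeds that of any beta distribution (v ≤ 0) the penalty is reported
  as not applicable rather than evaluated with negative shapes.
* `P_beta_order` — independent beta kernels with shapes (z+i−1, z+q−i) for
  the i-th smallest rescaled eigenvalue, the order-statistic distribution
  of a uniform sample at z = 0.
* `P_Sigma` / `P_Sigma2` — inverse-Wishart kernels C·log|Σ| + tr(Σ⁻¹Σ_P⁰)
  with C = (ψ+q+1)/ψ, shrinking Σ_G (and Σ_E for the two-part form) toward
  the unpenalized phenotypic matrix.  The objective uses the product
  ψ·C = ψ+q+1, well defined for all ψ ≥ 0; ψ = 0 bypasses penalization
  entirely.  A `c_approx_one` flag evaluates C = 1, the pure
  Kullback-Leibler form; both are available because either convention is
  defensible and they differ only at small ψ.
* `P_rho` / `P_rho2` — the same kernels on correlation matrices, shrinking
  R_G (and R_E) toward R_P⁰; invariant to trait rescaling, unlike
  `P_Sigma`.

Kernels are signed so every penalty is minimized at its target and ψ > 0
always shrinks.  Baseline quantities (λ⁰, Σ_P⁰, R_P⁰, moment shapes) are
frozen from the ψ = 0 fit before any penalized fit runs and are immutable
thereafter; in cross-validation they are re-derived inside each training
fold so no held-out information leaks.

## Optimization

Parameters are the canonical decomposition elements: Σ_G = TΛT',
Σ_E = T(I−Λ)T'.  The q eigenvalues are restrained to [0.0001, 0.9999]
through a logistic map from the real line, making Σ̂_G PSD and Σ̂_E PD by
construction; the q² elements of T are free.  Both strata factor as
T·D·T' with diagonal D (D_W = I − Λ/4, D_B = I + (n−1)Λ/4), which gives
closed-form gradients of the likelihood; the penalties' gradients are
also analytic, including the correlation-matrix chain rule
dP/dΣ = D^(−½)K D^(−½) − diag(diag(K·R)/diag(Σ)) for K = dP/dR.  A
bounded L-BFGS ascent (ftol 1e−12 on the objective, gradient tolerance
1e−5, 200-iteration cap) is followed by a compass search (coordinate
probes at steps 1e−4 → 1e−6, capped at 500 evaluations) that confirms no
further improvement; non-convergence is flagged, not raised.

Two numerical choices matter in practice.  First, non-PD strata inside
the search return an infinite objective so line searches retreat;
determinants and traces come from Cholesky factorizations, never explicit
inverses of near-singular matrices.  Second, warm-start points enter the
logistic map clipped to |u| ≤ 8: the map's gradient vanishes at extreme
u, so a start taken exactly at a pinned bound (λ̂ = 0.0001 from the
unpenalized fit) would freeze that eigenvalue even when the penalty wants
to lift it into the interior — precisely the situation shrinkage exists
for.  The optimizer itself may still travel to |u| = 25 to pin an
eigenvalue.

Tuning-factor paths are fitted sequentially over an ascending ψ grid,
each solution warm-starting the next, so the path follows one branch of
local maxima, mirroring a sequential ascending-psi search.  The standard grid has
311 values (0–2 by 0.1, 2.2–5 by 0.2, 5.5–10 by 0.5, 11–100 by 1,
102–250 by 2, 255–500 by 5, 510–1000 by 10).  For scaled-down work,
`thin_grid` subsamples within each constant-step segment, preserving the
dense low-ψ region where data-driven selection concentrates; uniform
thinning was found to starve the selection rules of candidates below
ψ = 2.

## Choosing the tuning factor

* **V∞** evaluates each path estimate's unpenalized likelihood on
  noiseless validation statistics M_B = Σ_B, M_W = Σ_W built from the
  population parameters — an oracle available only in simulation, used as
  the upper benchmark.
* **V1** does the same with a single extra simulated dataset.
* **CV(K)** assigns complete sire families to folds sequentially (family
  i → fold i mod K; each fold needs ≥ 2 families), fits a full path per
  training fold and maximizes the across-fold mean held-out likelihood.
  Folds are equally weighted.
* **L-limit** takes the largest grid ψ whose unpenalized-likelihood drop
  from the ψ = 0 maximum stays within δ = 1.92 = ½χ²₀.₀₅(1), i.e. a
  statistically non-significant change for one parameter — the pragmatic
  recommendation.  The "largest satisfying" rule is applied literally
  even on non-monotone drop curves.

## Simulation engine and scenario catalogue

The generator draws each family's mean from N(0, Σ_B/n) and its
within-family SSCP from Wishart(Σ_W, n−1) via the Bartlett construction —
exact in distribution and an order of magnitude faster than record-level
sampling, which is retained (and tested for distributional agreement) for
likelihood validation and raw-record export.  Per-family summaries are
kept so cross-validation can re-pool exact fold statistics.  Replicates
consume SeedSequence substreams, making results independent of execution
order.

The catalogue holds 90 scenarios: 12 heritability sets × correlation
scenarios I–V for q = 5 and 10 sets × I, VI, VII for q = 9, with
phenotypic-variance patterns tied to the correlation scenario.  Only the
equal-value sets (A, I, M, R), set T, and the constraints on the others
(group means 0.4/0.3/0.2, declining values, 0.80 spans for E, H, O,
marked unevenness for G, H, L, U, V) are pinned down; the remaining sets
are reconstructions satisfying those constraints, flagged
`reconstructed` in code and in scenario files.  Two reconstruction
choices are worth recording: minimum heritabilities were floored near
0.05 — the floor the one fully specified set uses — after floors of
0.01–0.02 produced pathological estimation behaviour out of character
with the study design; and set R's unstated mean was set to 0.3.
Correlation formulas bind a leading minus to the base of a power
((−0.8)^|i−j|, not −(0.8^|i−j|)); the alternative reading leaves scenario
IV non-positive-definite, which settles the ambiguity, but it remains
available as a convention flag for sensitivity checks.

What the generator does **not** emulate: unbalanced families, missing
records, pedigree structure beyond half-sibs, fixed effects beyond an
overall mean, selection, and non-normal traits.  Passing tests therefore
certify the estimator under the idealized design, not robustness to real
data's irregularities.

## Evaluation

Estimator quality uses the entropy loss L1 = tr(Σ⁻¹Σ̂) − log|Σ⁻¹Σ̂| − q and
quadratic loss L2 = tr(Σ⁻¹Σ̂ − I)²; the effect of penalization is the
percentage reduction in average loss, PRIAL = 100(L̄1⁰ − L̄1^ψ)/L̄1⁰, with
losses averaged over replicates before the ratio (not a mean of
per-replicate ratios).  Bias summaries report |θ̄̂ − θ| and 100(θ̄̂ − θ)/θ per
parameter plus the mean absolute deviation; for genetic correlations the
headline statistic is the mean over trait pairs of the absolute
per-pair replicate-mean deviation.  Note this statistic is inflated at
small replicate counts (|·| of a noisy mean), so replicate counts are
reported with every aggregate along with Monte-Carlo standard errors
(bootstrap over replicates for ratio statistics).

## Problem sizes used in the shipped checks

The test suite runs the fully specified nine-trait scenario (T-VI,
s = 100, n = 10) at 500 replicates and the qualitative penalty/strategy
comparisons at 12 replicates on segment-thinned grids; the acceptance
script uses 1000 replicates for T-VI (the study's own count) and 500 per
scenario across the 60 five-trait catalogue entries.  These sizes keep
each aggregate's Monte-Carlo standard error a small fraction of the
effects being measured; anything larger changes the numbers only within
those errors.

## Known limitations

* Only the balanced half-sib likelihood is implemented; general pedigrees
  and arbitrary fixed effects are out of scope.
* Warm-started path following accepts the local maximum reachable from
  the previous ψ; no multi-start search for competing branches.
* The catalogue's reconstructed heritability sets make catalogue-mean
  statistics approximate; per-scenario results for the fully specified
  scenarios (A-I, I-*, M-I, R-I, T-VI) are exact reproductions of the
  study conditions.
* Separate genetic/residual tuning factors for the two-part penalties are
  implemented but no 2-D search strategy is provided; callers must supply
  the (ψ_G, ψ_E) pair.
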