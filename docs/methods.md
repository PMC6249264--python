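# Methods

## Model and estimation

The variance-components model is `y ~ N(Xβ, σ_p²·V_h2)` with
`V_h2 = h²K + (1−h²)I` and `σ_p² = σ_g² + σ_e²`. All likelihood work
happens in the eigenbasis of K. Eigenvalues are declared "retained" when
`d_i > 1e-8 · max(d)` — a relative threshold, so centering (the constant
vector is a null eigenvector of any kinship built from column-centered
genotypes) and low rank (m < n markers) are detected regardless of scale.
The phenotype and covariates are projected onto the z retained
eigenvectors; covariate columns annihilated by that projection (the
intercept, for a centered kinship) are dropped and the residual degrees of
freedom are `z − p_eff`. V is then diagonal, so one restricted-likelihood
evaluation costs O(z·p_eff²).

β is profiled by GLS and σ_p² in closed form, leaving a one-dimensional
problem in h². `reml_fit` scans a 101-point grid on [0, 1], refines the
best bracket with a bounded scalar minimizer (xatol 1e-8), and — when the
optimum is interior — polishes it with a Brent root-find on the analytic
profile derivative (xtol 1e-14). The polish matters: the anchor H² = ĥ²(y)
is consumed by a *sign* test, and an anchor that is a true derivative root
guarantees the unpermuted phenotype itself is classified by the tie
convention rather than by optimizer noise. Estimates within 1e-6 of 0 or 1
are snapped to the boundary and flagged (`at_zero` / `at_one`); a
numerically flat likelihood (K ≈ I) returns ĥ² = 0 with `at_zero`, the
conservative convention for an unidentifiable h².

The parametric test uses `2·(ℓ_alt − ℓ_null)` against the boundary mixture
`0.5·χ²₀ + 0.5·χ²₁`; the statistic is clamped to 0 below 1e-8 in
magnitude, and a statistic below −1e-6 raises (it signals an optimizer
failure, not randomness). The log-likelihood uses the standard −½(...)
convention with 2π constants dropped; only differences are meaningful.

## Derivative-sign test

For an intercept-only design over a centered kinship the exceedance
decision `ĥ²(π(y)) ≥ H²` equals the sign of `Σ ξᵢuᵢ²`, `u = Uᵀπ(y)`, with

```
ξ_i = [ (d_i−1)/v_i − mean_j (d_j−1)/v_j ] / v_i ,   v_i = H²(d_i−1)+1 ,
```

the mean over the z retained eigenvalues and ξ = 0 on discarded
coordinates. With exactly one discarded (null) eigenvalue this is the
classical n−1-term expression; in general it is, verbatim, the analytic
derivative of the *projected* profiled restricted likelihood specialized
to p_eff = 0 — so the sign test and `reml_fit` always refer to the same
likelihood. The derivation was re-checked against central finite
differences (step 1e-6) and the dense-matrix likelihood in the tests. For
general covariates the derivative is evaluated analytically in the rotated
basis at O(z·p² + p³) per permutation after the O(n²) rotation.

Numerical conventions: quadratic forms with `|Σξu²| < 1e-12·‖u‖²` are
ties (sign 0), and ties count as exceeding — the test errs conservative,
matching the ≥ in the p-value definition. An anchor of H² = 0 makes every
permutation exceed, so non-heritable-looking phenotypes get p = 1 without
drawing a single permutation.

### Unimodality guard

The sign-at-the-anchor shortcut presumes a single-maximum profile
likelihood. At small n (≲ 100, and routinely at n ≤ 12) a visible fraction
of permuted phenotypes — 0.1–2% in our n=7–8 enumerations — have U-shaped
profiles whose maxima at both boundaries compete; the bare sign then
misclassifies the decision. All decision paths therefore inspect the
derivative sign at the anchor grid {0, H²/2, H², (1+H²)/2, 1−1e-6}: a sign
that rises again after having fallen is impossible under unimodality, and
flagged permutations are re-decided by a full (batched) REML fit. The
guard is O(n) per permutation on top of the single n × n matrix–vector
product, so the cost contract is unchanged; `check_unimodal=False`
restores the bare single-sign decision. SAMC's interval location applies
the same pattern check when `check_unimodal=True` is requested; its
compiled kernel runs the plain binary search, which the factor-two
accuracy checks absorb.

## Monte Carlo permutation test

N permutations are drawn i.i.d. (with replacement) in fixed 8192-wide
blocks, each block from its own counter-based Philox stream seeded by
`SeedSequence([seed, block])` — counts are reproducible and independent of
execution order or threading. p_mc = b/N exactly (no +1 smoothing; the
printed definition), with exact Clopper–Pearson intervals from beta
quantiles; screening decisions use the CI, never the point estimate. With
non-constant covariates the same permutation is applied jointly to y and
every covariate row; exchangeability of residuals then holds only
approximately, which is documented rather than enforced. Rule of thumb:
estimating p ≈ 1/M needs ~100·M permutations — beyond that, use SAMC.

## SAMC

`[0, H²]` is split into D equal intervals plus the tail `[H², 1]` (D+1
subsets of the permutation space; the p-value is the relative size of the
tail subset). One chain iteration proposes a single uniform transposition
(symmetric, so the MH ratio reduces to `exp(θ_J(π) − θ_J(τ))`), locates
the proposal's interval by O(log D) derivative signs on an incrementally
updated rotated phenotype (`u += (U_i − U_j)·δ`, O(n); fully recomputed
every 10,000 accepted moves to bound drift), accepts with min(1, r), and
applies the gain-factor update `θ ← θ + γ_t(e_J − 1/(D+1))` with
`γ_t = t₀/max(t₀, t)` (so Σθ is conserved and `γ_t → 0, Σγ_t = ∞`).
Defaults D = 50, t₀ = 1000, N = 10⁶. The estimate
`exp(θ_{D+1})/Σexp(θᵢ)` is computed via log-sum-exp; before any iteration
it is the uniform 1/(D+1). Intervals whose subset is empty simply drift
down via the −γ/(D+1) term and normalize away.

Convergence reporting is our own choice (the printed algorithm defers
diagnostics): θ is checkpointed 10 times per run and the run is flagged
non-converged when the last two checkpoint estimates differ by more than
0.1 in log10. The chain is inherently sequential; one seed governs the
start permutation and the whole proposal stream (parallelism belongs
across phenotypes, not within a chain). The hot loop is a numba kernel;
the pure-Python `mh_step`/`samc_update`/`interval_of` operations implement
the identical update rules and are cross-checked against exhaustive
enumeration in the tests.

## Screening pipeline

For panels sharing one kinship: per round (default 100, 1k, 10k, 100k
permutations — a stated 10× escalation), any phenotype whose one-sided
lower confidence bound on p (exact binomial by default; Poisson χ² form
optionally, for b ≪ N) exceeds the significance threshold α is finalized
as non-significant; ĥ² = 0 phenotypes are finalized immediately with
p = 1. Survivors of the last round go to SAMC — except anchors at ĥ² = 1,
where the partition is undefined and the last Monte Carlo estimate is
reported (`mc_final`). The filter is conservative: a truly significant
phenotype is discarded with probability at most the CI error rate. The
eigendecomposition and per-anchor ξ weights are computed once per kinship.

## Synthetic data

`simulate_genotypes` draws binomial(2, MAF) dosages (MAF uniform on
[0.05, 0.5] by default), resamples monomorphic columns, and
column-standardizes; K = ZZᵀ/m is then centered so the intercept-mode
eigenstructure holds. `simulate_lmm_phenotype` draws exactly from
N(Xβ, σ_p²(h²K + (1−h²)I)) through the eigenbasis. Exchangeable non-normal
nulls are i.i.d. Student-t (df > 2 enforced — an infinite variance has no
LMM heritability interpretation) or lognormal; methylation-like phenotypes
are two-component beta mixtures (Beta(2,8) + Beta(8,2) at equal weight by
default), with a third component for tri-modal sites. Quantile
normalization is the rank-based inverse-normal transform
Φ⁻¹((rank − 0.5)/n) with average ranks on ties (the dialect is our
choice; the transform is named, not specified, in the literature it comes
from). No linkage disequilibrium, batch effects, imputation artifacts or
ascertainment are emulated — passing tests say the machinery is correct
under the stated model, not that real cohorts behave this way.

### Study sizes used by the tests and the acceptance script

All sizes are desk-scale choices so the whole suite runs in minutes on
one CPU:

* **Type-I error**: n=50 individuals, m=500 markers, 5,000 null
  phenotypes, 2,000 permutations each. At this size the null REML
  estimate has a sizable boundary atom (P(ĥ² = 1) ≈ 6.5%), which floors
  the attainable permutation p-value near 0.07: the measured fraction
  with p < 0.001 is 0 rather than the nominal 0.1% that holds in the
  continuum (large-n) regime. The test remains valid — super-uniform —
  and the measured value is reported as computed.
* **Small-p instances** (SAMC cross-validation): a cis-window-like
  kinship with m = n = 50 and phenotypes at h² = 0.65, where p-values in
  [10⁻³, 10⁻²] actually occur; the flat spectrum of an m ≫ n kinship at
  n = 50 cannot reach them.
* **Miscalibration demonstration**: i.i.d. lognormal(0, 2) nulls over an
  m = n = 100 kinship, where the parametric LRT rejects at α = 10⁻³
  about 4× nominal while the permutation test stays at nominal. Student-t(3)
  tails inflate the LRT too, but too weakly at these n to resolve within a
  desk-scale simulation budget.
* **Exhaustive oracles**: n = 7 and 8, where all n! permutations are
  enumerated with (vectorized) full REML.

## Known limitations

* One variance component; no GLMMs, case-control ascertainment
  corrections, or multiple kinships.
* Intercept-mode fast paths require a centered kinship; otherwise the
  general-covariate path (slower per permutation) is used automatically.
* SAMC needs an interior anchor H² ∈ (0, 1) and runs single-chain.
* The unimodality guard inspects five anchors; profiles that oscillate
  strictly between adjacent anchors would evade it (never observed in the
  enumerations).
* Exchangeability with non-constant covariates is approximate; the
  package permutes covariates jointly with the phenotype and documents,
  rather than tests, the conditions under which this is exact.
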