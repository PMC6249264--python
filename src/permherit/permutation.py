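"""Monte Carlo permutation testing for heritability.

The permutation p-value is the fraction of relabelings whose REML
heritability estimate is at least the observed one,

    p_perm = |{pi : h2_hat(pi(y)) >= h2_hat(y)}| / n!,

approximated by N i.i.d. uniform random permutations, so the exceedance
count b is binomial and exact Clopper-Pearson intervals apply. Covariates
(when non-constant) are permuted jointly with the phenotype. As a rule of
thumb, accurately estimating a p-value of 1/M by plain Monte Carlo takes
about 100*M permutations; for smaller p-values use the SAMC estimator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .derivative import DerivativeContext, guard_anchors
from .kinship import EigenKinship
from .lmm import PhenotypeStudy, RotatedStudy, reml_fit

__all__ = [
    "PermutationResult",
    "permute_dataset",
    "clopper_pearson_ci",
    "one_sided_lower_bound",
    "mc_permutation_pvalue",
    "exhaustive_permutation_pvalue",
]

#: permutations are drawn in fixed-size blocks, each from its own
#: counter-based stream, so counts do not depend on execution order
STREAM_BLOCK = 8192


@dataclass(frozen=True)
class PermutationResult:
    p_mc: float
    exceed_count: int
    n_perms: int
    ci: tuple
    ci_level: float
    seed: int
    anchor: float


def permute_dataset(study: PhenotypeStudy, perm: np.ndarray) -> PhenotypeStudy:
    """Apply one permutation jointly to the phenotype and every covariate row.

    The kinship is left untouched: relabeling individuals relative to a
    fixed relatedness structure is exactly the exchangeability null.
    """
    perm = np.asarray(perm)
    n = study.n
    if perm.shape != (n,) or not np.array_equal(np.sort(perm), np.arange(n)):
        raise ValueError("perm is not a bijection on 0..n-1")
    labels = study.labels[perm] if study.labels is not None else None
    return PhenotypeStudy(y=study.y[perm], X=study.X[perm, :], labels=labels)


def clopper_pearson_ci(b: int, N: int, level: float = 0.95) -> tuple:
    """Exact (beta-quantile) binomial confidence interval for b/N."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if not 0 <= b <= N:
        raise ValueError(f"need 0 <= b <= N, got b={b}, N={N}")
    alpha = 1.0 - level
    lo = 0.0 if b == 0 else float(scipy.stats.beta.ppf(alpha / 2, b, N - b + 1))
    hi = 1.0 if b == N else float(scipy.stats.beta.ppf(1 - alpha / 2, b + 1, N - b))
    return (lo, hi)


def one_sided_lower_bound(
    b: int, N: int, level: float = 0.99, method: str = "binomial"
) -> float:
    """One-sided lower confidence bound on the true p-value given b/N.

    ``poisson`` uses the chi-square form of the exact Poisson bound,
    appropriate when b << N.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if b == 0:
        return 0.0
    if method == "binomial":
        return float(scipy.stats.beta.ppf(1.0 - level, b, N - b + 1))
    if method == "poisson":
        return float(scipy.stats.chi2.ppf(1.0 - level, 2 * b) / 2.0 / N)
    raise ValueError(f"unknown lower-bound method {method!r}")


def _perm_blocks(seed: int, n: int, n_perms: int):
    """Yield (block_index, perms) with per-block counter-based streams."""
    base = np.arange(n)
    produced = 0
    block = 0
    while produced < n_perms:
        take = min(STREAM_BLOCK, n_perms - produced)
        rng = np.random.Generator(
            np.random.Philox(np.random.SeedSequence([int(seed), block]))
        )
        perms = rng.permuted(np.tile(base, (take, 1)), axis=1)
        yield block, perms
        produced += take
        block += 1


def mc_permutation_pvalue(
    study: PhenotypeStudy,
    ctx: DerivativeContext,
    H2: float,
    n_perms: int,
    seed: int,
    ci_level: float = 0.95,
    use_derivative: bool = True,
    check_unimodal: bool = True,
) -> PermutationResult:
    """Plain Monte Carlo permutation p-value at anchor H2 = h2_hat(y).

    The derivative path costs one n x n matrix-vector product per
    permutation (batched into matrix-matrix products) plus O(n) sign
    arithmetic. With ``check_unimodal`` (default) the derivative sign is
    inspected at a small anchor grid; permutations whose sign pattern
    betrays a multi-modal profile (possible at small n) are re-decided by
    full REML estimation, keeping the count faithful to the estimate
    comparison. ``use_derivative=False`` runs a full REML fit for every
    permutation and exists as the slow reference.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if np.ptp(study.y) == 0:
        raise ValueError("degenerate (constant) phenotype: anchor undefined")
    if H2 <= 0.0:
        # every permuted estimate is >= 0, so the test is vacuous: p = 1
        b = n_perms
        return PermutationResult(
            1.0, b, n_perms, clopper_pearson_ci(b, n_perms, ci_level), ci_level,
            int(seed), float(H2),
        )
    y = study.y
    b = 0
    if use_derivative and ctx.mode == "intercept_only":
        z = ctx.eig.z
        Uz = ctx.basis[:, :z]
        anchors, iH = guard_anchors(H2)
        Xi = np.stack([ctx.weights(h).xi[:z] for h in anchors])  # (G, z)
        tol = 1e-12 * float(y @ y)  # ||u||^2 == ||y||^2: U orthonormal
        for _, perms in _perm_blocks(seed, study.n, n_perms):
            W = np.square(y[perms] @ Uz)  # (B, z)
            S = W @ Xi.T  # (B, G)
            dec = S[:, iH] > -tol
            if check_unimodal:
                sgn = np.where(S > tol, 1, np.where(S < -tol, -1, 0))
                neg_seen = np.cumsum(sgn < 0, axis=1) > 0
                rise_after_fall = np.any(
                    (sgn[:, 1:] > 0) & neg_seen[:, :-1], axis=1
                )
                if rise_after_fall.any():
                    h2_flagged = _batched_h2_hat(
                        y[perms[rise_after_fall]], ctx.eig
                    )
                    dec[rise_after_fall] = h2_flagged >= H2 - 1e-8
            b += int(np.count_nonzero(dec))
    elif use_derivative:
        anchors, iH = guard_anchors(H2)
        for _, perms in _perm_blocks(seed, study.n, n_perms):
            for perm in perms:
                permuted = permute_dataset(study, perm)
                local = DerivativeContext(
                    eig=ctx.eig, mode="general_X",
                    X_rot=ctx.eig.U_z.T @ permuted.X,
                )
                sgn = [local.derivative_sign_at(permuted.y, h) for h in anchors]
                falls = [i for i, s in enumerate(sgn) if s < 0]
                multimodal = check_unimodal and falls and any(
                    s > 0 for s in sgn[falls[0] + 1 :]
                )
                if multimodal:
                    if reml_fit(permuted, ctx.eig).h2_hat >= H2 - 1e-8:
                        b += 1
                elif sgn[iH] >= 0:
                    b += 1
    else:
        for _, perms in _perm_blocks(seed, study.n, n_perms):
            for perm in perms:
                permuted = permute_dataset(study, perm)
                if reml_fit(permuted, ctx.eig).h2_hat >= H2:
                    b += 1
    return PermutationResult(
        p_mc=b / n_perms,
        exceed_count=b,
        n_perms=n_perms,
        ci=clopper_pearson_ci(b, n_perms, ci_level),
        ci_level=ci_level,
        seed=int(seed),
        anchor=float(H2),
    )


def _batched_h2_hat(Y: np.ndarray, eig: EigenKinship, coarse: int = 257) -> np.ndarray:
    """Vectorized intercept-only REML h2_hat for many phenotypes at once.

    Coarse grid scan over h2 followed by a vectorized golden-section
    refinement of every phenotype's bracket; used by the exhaustive oracle
    where millions of scalar optimizations would be prohibitive.
    """
    Uz = eig.U_z
    d = eig.d_z
    z = eig.z
    ones = np.ones(eig.n) / math.sqrt(eig.n)
    if np.linalg.norm(Uz.T @ ones) > 1e-6:
        raise ValueError("batched intercept-only REML requires a centered kinship")
    W = np.square(Y @ Uz)  # (P, z) rotated squared phenotypes

    def negll(h):  # h: (P,) or scalar; returns (P,)
        h = np.asarray(h)
        v = np.multiply.outer(h, d - 1.0) + 1.0  # (..., z)
        s2 = (W * (1.0 / v)).sum(axis=-1) / z
        return z * np.log(s2) + np.log(v).sum(axis=-1)

    grid = np.linspace(0.0, 1.0, coarse)
    vals = np.stack([negll(h) for h in grid])  # (G, P)
    idx = vals.argmin(axis=0)
    lo = grid[np.maximum(idx - 1, 0)]
    hi = grid[np.minimum(idx + 1, coarse - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, bb = lo.copy(), hi.copy()
    for _ in range(45):
        c = bb - invphi * (bb - a)
        e = a + invphi * (bb - a)
        left = negll(c) < negll(e)
        bb = np.where(left, e, bb)
        a = np.where(left, a, c)
    h2 = 0.5 * (a + bb)
    # boundary candidates beat interior refinements where appropriate
    cand = np.stack([h2, np.zeros_like(h2), np.ones_like(h2)])
    cand_vals = np.stack([negll(h2), vals[0], vals[-1]])
    return cand[cand_vals.argmin(axis=0), np.arange(Y.shape[0])]


def exhaustive_permutation_pvalue(
    study: PhenotypeStudy,
    eig: EigenKinship,
    anchor: float | None = None,
    batch: int = 8192,
    return_estimates: bool = False,
):
    """Exact p_perm by enumerating all n! permutations with full REML.

    Intercept-only designs, n <= 9. Returns p_perm (and, optionally, the
    array of per-permutation heritability estimates in lexicographic
    permutation order).
    """
    n = study.n
    if n > 9:
        raise ValueError("exhaustive enumeration is limited to n <= 9")
    if not study.is_intercept_only():
        raise ValueError("exhaustive oracle supports intercept-only designs")
    if anchor is None:
        anchor = reml_fit(study, eig).h2_hat
    y = study.y
    estimates = np.empty(math.factorial(n))
    pos = 0
    it = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(it, batch))
        if not chunk:
            break
        P = np.array(chunk)
        estimates[pos : pos + len(chunk)] = _batched_h2_hat(y[P], eig)
        pos += len(chunk)
    p_perm = float(np.mean(estimates >= anchor - 1e-8))
    if return_estimates:
        return p_perm, estimates
    return p_perm
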