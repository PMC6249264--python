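"""Gradual screening of many phenotypes sharing one kinship.

Most phenotypes in a genome- or epigenome-wide panel are far from the
multiple-testing threshold, so spending a large permutation budget on each
is wasteful. The screen runs cheap plain-permutation rounds with escalating
counts (default 100, 1k, 10k, 100k); after each round a phenotype whose
one-sided lower confidence bound on the p-value already exceeds alpha is
finalized as non-significant. Survivors of the last round — the only ones
that can still be significant — go to SAMC. The filter is conservative:
a phenotype with true p <= alpha is wrongly discarded at most at the CI's
error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .derivative import DerivativeContext
from .kinship import EigenKinship
from .lmm import PhenotypeStudy, lrt_pvalue, reml_fit, reml_loglik
from .permutation import mc_permutation_pvalue, one_sided_lower_bound
from .samc import samc_pvalue

__all__ = ["ScreenSchedule", "screen"]


@dataclass(frozen=True)
class ScreenSchedule:
    """Escalating permutation rounds and the CI-based filter settings."""

    rounds: Sequence[int] = (100, 1_000, 10_000, 100_000)
    alpha: float = 1e-3
    ci_level: float = 0.99
    lower_bound_method: str = "binomial"  # or 'poisson' for b << N

    def __post_init__(self):
        r = tuple(self.rounds)
        if len(r) < 1 or any(x <= 0 for x in r):
            raise ValueError("rounds must be positive permutation counts")
        if list(r) != sorted(set(r)):
            raise ValueError("rounds must be strictly increasing")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def screen(
    studies: Sequence[PhenotypeStudy],
    eig: EigenKinship,
    schedule: Optional[ScreenSchedule] = None,
    samc_params: Optional[dict] = None,
    seed: int = 0,
    ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Screen a panel of phenotypes sharing one kinship eigendecomposition.

    Returns one row per phenotype: id, h2_hat, parametric_p, status
    ('h2_zero', 'filtered_round_k', 'mc_final', 'samc_estimated'),
    p_final, ci_lo, ci_hi, n_perms_used.
    """
    schedule = schedule or ScreenSchedule()
    samc_params = dict(samc_params or {})
    samc_params.setdefault("D", 50)
    samc_params.setdefault("t0", 1000)
    samc_params.setdefault("n_iter", 1_000_000)
    if ids is None:
        ids = [f"pheno_{k}" for k in range(len(studies))]
    rows = []
    # the eigendecomposition and per-anchor weights are shared; contexts
    # differ only when covariate designs differ
    for k, study in enumerate(studies):
        fit = reml_fit(study, eig)
        ll0 = reml_loglik(study, eig, 0.0)
        parametric_p = lrt_pvalue(fit, ll0)
        ctx = DerivativeContext.build(eig, None if study.is_intercept_only() else study.X)
        row = {
            "id": ids[k],
            "h2_hat": fit.h2_hat,
            "parametric_p": parametric_p,
        }
        if fit.h2_hat == 0.0:
            rows.append({**row, "status": "h2_zero", "p_final": 1.0,
                         "ci_lo": np.nan, "ci_hi": np.nan, "n_perms_used": 0})
            continue
        finalized = False
        total_perms = 0
        res = None
        for r_idx, n_perms in enumerate(schedule.rounds, start=1):
            res = mc_permutation_pvalue(
                study, ctx, fit.h2_hat, n_perms,
                seed=int(np.random.SeedSequence([seed, k, r_idx]).generate_state(1)[0] % (2**31)),
                ci_level=schedule.ci_level,
            )
            total_perms += n_perms
            lo = one_sided_lower_bound(
                res.exceed_count, n_perms, schedule.ci_level,
                schedule.lower_bound_method,
            )
            if lo > schedule.alpha:
                rows.append({**row, "status": f"filtered_round_{r_idx}",
                             "p_final": res.p_mc, "ci_lo": res.ci[0],
                             "ci_hi": res.ci[1], "n_perms_used": total_perms})
                finalized = True
                break
        if finalized:
            continue
        if fit.h2_hat >= 1.0 or ctx.mode != "intercept_only":
            # SAMC needs an interior anchor and the intercept-only fast
            # path; otherwise the last plain-MC round is the best estimate
            rows.append({**row, "status": "mc_final", "p_final": res.p_mc,
                         "ci_lo": res.ci[0], "ci_hi": res.ci[1],
                         "n_perms_used": total_perms})
            continue
        sres = samc_pvalue(
            study, ctx, fit.h2_hat,
            seed=int(np.random.SeedSequence([seed, k, 999]).generate_state(1)[0] % (2**31)),
            **samc_params,
        )
        rows.append({**row, "status": "samc_estimated", "p_final": sres.p_value,
                     "ci_lo": np.nan, "ci_hi": np.nan,
                     "n_perms_used": total_perms + sres.n_iter})
    return pd.DataFrame(rows)
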