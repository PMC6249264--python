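"""Model/results façade over the heritability testing machinery.

``HeritabilityLMM`` holds one phenotype, its covariate design and a kinship
eigendecomposition; ``fit()`` runs REML and returns a
``HeritabilityResults`` carrying the estimates, the parametric LRT
p-value, and methods for permutation-based and SAMC p-values.
"""

from __future__ import annotations

from functools import cached_property
from typing import Optional

import numpy as np
import pandas as pd

from .derivative import DerivativeContext
from .kinship import EigenKinship, Kinship, eigendecompose
from .lmm import PhenotypeStudy, RemlFit, lrt_pvalue, lrt_statistic, reml_fit, reml_loglik
from .permutation import PermutationResult, mc_permutation_pvalue
from .samc import SAMCResult, samc_pvalue

__all__ = ["HeritabilityLMM", "HeritabilityResults"]


class HeritabilityLMM:
    """Linear mixed model y ~ N(X beta, sigma_g^2 K + sigma_e^2 I).

    Parameters
    ----------
    endog : (n,) phenotype vector.
    exog : (n, p) covariate matrix; defaults to an intercept column.
    kinship : (n, n) relatedness matrix, or a precomputed ``EigenKinship``
        via ``eig=``. Exactly one of the two must be given.
    """

    def __init__(self, endog, exog=None, kinship=None, eig: Optional[EigenKinship] = None,
                 labels=None):
        if (kinship is None) == (eig is None):
            raise ValueError("supply exactly one of kinship or eig")
        self.eig = eig if eig is not None else eigendecompose(kinship)
        self.study = PhenotypeStudy(y=endog, X=exog, labels=labels)
        if self.study.n != self.eig.n:
            raise ValueError("phenotype and kinship sizes differ")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, phenotype: str,
                       covariates: Optional[list] = None, kinship=None,
                       eig: Optional[EigenKinship] = None) -> "HeritabilityLMM":
        y = data[phenotype].to_numpy(dtype=float)
        X = None
        if covariates:
            X = np.column_stack(
                [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in covariates]
            )
        return cls(y, exog=X, kinship=kinship, eig=eig,
                   labels=data.index.to_numpy())

    @cached_property
    def _ctx(self) -> DerivativeContext:
        X = None if self.study.is_intercept_only() else self.study.X
        return DerivativeContext.build(self.eig, X)

    def loglike(self, h2: float) -> float:
        return reml_loglik(self.study, self.eig, h2)

    def fit(self) -> "HeritabilityResults":
        return HeritabilityResults(self, reml_fit(self.study, self.eig))


class HeritabilityResults:
    """REML estimates plus parametric and permutation-based tests."""

    def __init__(self, model: HeritabilityLMM, fit: RemlFit):
        self.model = model
        self._fit = fit

    @property
    def h2(self) -> float:
        return self._fit.h2_hat

    @property
    def sigma_p2(self) -> float:
        return self._fit.sigma_p2_hat

    @property
    def sigma_g2(self) -> float:
        return self._fit.sigma_g2_hat

    @property
    def sigma_e2(self) -> float:
        return self._fit.sigma_e2_hat

    @property
    def params(self) -> np.ndarray:
        return self._fit.beta_hat

    @property
    def llf(self) -> float:
        return self._fit.loglik

    @property
    def boundary(self) -> str:
        return self._fit.boundary

    @cached_property
    def llnull(self) -> float:
        return reml_loglik(self.model.study, self.model.eig, 0.0)

    @property
    def lrt_stat(self) -> float:
        return lrt_statistic(self._fit, self.llnull)

    @property
    def lrt_pvalue(self) -> float:
        """Parametric p-value from the 0.5*chi2_0 + 0.5*chi2_1 boundary null."""
        return lrt_pvalue(self._fit, self.llnull)

    def permutation_test(self, n_perms: int = 10_000, seed: int = 0,
                         ci_level: float = 0.95) -> PermutationResult:
        """Plain Monte Carlo permutation p-value anchored at the estimate."""
        return mc_permutation_pvalue(
            self.model.study, self.model._ctx, self.h2, n_perms, seed, ci_level
        )

    def samc(self, D: int = 50, t0: int = 1000, n_iter: int = 1_000_000,
             seed: int = 0, **kw) -> SAMCResult:
        """SAMC p-value estimate for small-p regimes."""
        return samc_pvalue(self.model.study, self.model._ctx, self.h2,
                           D=D, t0=t0, n_iter=n_iter, seed=seed, **kw)

    def summary(self) -> str:
        fit = self._fit
        lines = [
            "Heritability LMM (REML)",
            "=" * 46,
            f"{'n individuals':<28}{self.model.study.n:>18}",
            f"{'retained eigenvalues (z)':<28}{self.model.eig.z:>18}",
            f"{'covariates (p)':<28}{self.model.study.p:>18}",
            "-" * 46,
            f"{'h2_hat':<28}{fit.h2_hat:>18.6f}",
            f"{'sigma_p2_hat':<28}{fit.sigma_p2_hat:>18.6f}",
            f"{'sigma_g2_hat':<28}{fit.sigma_g2_hat:>18.6f}",
            f"{'sigma_e2_hat':<28}{fit.sigma_e2_hat:>18.6f}",
            f"{'boundary':<28}{fit.boundary:>18}",
            f"{'restricted loglik':<28}{fit.loglik:>18.6f}",
            f"{'LRT statistic':<28}{self.lrt_stat:>18.6f}",
            f"{'parametric p (mixture)':<28}{self.lrt_pvalue:>18.3e}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<HeritabilityResults h2={self.h2:.4f} "
                f"p_param={self.lrt_pvalue:.3e} boundary={self.boundary}>")
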