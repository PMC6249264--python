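"""Synthetic genotypes, kinships and phenotypes for testing and calibration.

The generator produces three phenotype regimes:

* LMM draws at a chosen true heritability — for estimator recovery and
  power checks;
* exchangeable non-normal nulls (heavy-tailed Student-t, lognormal) —
  the regime where the parametric LRT miscalibrates while the permutation
  test, exact under exchangeability, stays at nominal level;
* bounded bimodal beta-mixture values mimicking methylation proportions
  (with an optional third component for tri-modal sites).

Genotypes are binomial(2, MAF) dosages, column-standardized, so the
default kinship Z Z^T / m is column-centered and the intercept-only fast
path applies. No linkage structure, batch effects, or missingness are
emulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .kinship import EigenKinship, GenotypeMatrix, build_kinship, eigendecompose
from .lmm import PhenotypeStudy

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_lmm_phenotype",
    "simulate_nonnormal_null",
    "simulate_methylation_like",
    "quantile_normalize",
    "simulate_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults describe the standard small-cohort testbed: n=50 individuals
    typed at m=500 common markers (MAF uniform on [0.05, 0.5]), total
    phenotypic variance 1.
    """

    n: int = 50
    m: int = 500
    maf_range: tuple = (0.05, 0.5)
    h2_true: float = 0.0
    sigma_p2: float = 1.0
    noise: str = "gaussian"  # gaussian | student_t | lognormal | beta_mixture
    t_df: float = 3.0
    lognormal_sigma: float = 1.0
    beta_components: Sequence[tuple] = ((2.0, 8.0), (8.0, 2.0))
    beta_weights: Sequence[float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 0.5 + 1e-12:
            raise ValueError("need 0 < maf_lo <= maf_hi <= 0.5")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must lie in [0, 1]")


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Binomial(2, MAF) dosages per marker, column-standardized.

    Monomorphic columns (possible at small n and low MAF) are resampled.
    """
    if cfg.n < 2 or cfg.m < 2:
        raise ValueError("need n >= 2 and m >= 2")
    rng = np.random.default_rng(cfg.seed)
    mafs = rng.uniform(*cfg.maf_range, size=cfg.m)
    G = rng.binomial(2, mafs, size=(cfg.n, cfg.m)).astype(float)
    while True:
        mono = np.ptp(G, axis=0) == 0
        if not mono.any():
            break
        k = int(mono.sum())
        G[:, mono] = rng.binomial(2, mafs[mono], size=(cfg.n, k))
    return GenotypeMatrix((G - G.mean(axis=0)) / G.std(axis=0))


def simulate_lmm_phenotype(
    eig: EigenKinship,
    X: Optional[np.ndarray],
    beta: Optional[np.ndarray],
    h2: float,
    sigma_p2: float,
    seed: int,
) -> np.ndarray:
    """Draw y ~ N(X beta, sigma_p2 * (h2 K + (1-h2) I)) via the eigenbasis."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    if sigma_p2 <= 0:
        raise ValueError("sigma_p2 must be positive")
    rng = np.random.default_rng(seed)
    d = eig.d
    if np.any(d < 0):
        if d.min() < -1e-10 * max(d.max(), 1.0):
            warnings.warn("clamping numerically negative eigenvalues at 0")
        d = np.maximum(d, 0.0)
    scale = np.sqrt(sigma_p2 * (h2 * d + (1.0 - h2)))
    y = eig.U @ (scale * rng.standard_normal(eig.n))
    if X is not None and beta is not None:
        y = y + np.asarray(X) @ np.asarray(beta)
    return y


def simulate_nonnormal_null(cfg: SimConfig) -> np.ndarray:
    """I.i.d. (hence exchangeable) heavy-tailed draws: zero true heritability."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise == "student_t":
        if cfg.t_df <= 2:
            raise ValueError(
                "Student-t requires df > 2: an undefined variance has no "
                "heritability interpretation under the LMM"
            )
        return rng.standard_t(cfg.t_df, size=cfg.n)
    if cfg.noise == "lognormal":
        return rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=cfg.n)
    raise ValueError(f"not a non-normal null family: {cfg.noise!r}")


def simulate_methylation_like(cfg: SimConfig) -> np.ndarray:
    """Beta-mixture proportions in (0, 1); bimodal by default, tri-modal
    when a third component is configured."""
    w = np.asarray(cfg.beta_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("beta mixture weights must sum to 1")
    if len(w) != len(cfg.beta_components):
        raise ValueError("one weight per beta component required")
    rng = np.random.default_rng(cfg.seed)
    comp = rng.choice(len(w), size=cfg.n, p=w)
    ab = np.asarray(cfg.beta_components, dtype=float)
    return rng.beta(ab[comp, 0], ab[comp, 1])


def quantile_normalize(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((rank - 0.5) / n).

    Ties get average ranks; invariant under monotone transforms of y.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("cannot quantile-normalize a constant vector")
    ranks = scipy.stats.rankdata(y, method="average")
    return scipy.stats.norm.ppf((ranks - 0.5) / y.shape[0])


def simulate_study(cfg: SimConfig):
    """One self-contained dataset: kinship eigendecomposition + phenotype.

    Gaussian noise draws from the LMM at ``cfg.h2_true``; the other noise
    families produce exchangeable nulls. Returns (study, eig, manifest)
    where the manifest records the generating truth.
    """
    Z = simulate_genotypes(cfg)
    eig = eigendecompose(build_kinship(Z))
    if cfg.noise == "gaussian":
        y = simulate_lmm_phenotype(
            eig, None, None, cfg.h2_true, cfg.sigma_p2, seed=cfg.seed + 1
        )
        truth_h2 = cfg.h2_true
    elif cfg.noise == "beta_mixture":
        y = simulate_methylation_like(
            SimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        )
        truth_h2 = 0.0
    else:
        y = simulate_nonnormal_null(
            SimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        )
        truth_h2 = 0.0
    study = PhenotypeStudy(y=y)
    manifest = {
        "n": cfg.n,
        "m": cfg.m,
        "noise": cfg.noise,
        "h2_true": truth_h2,
        "sigma_p2": cfg.sigma_p2,
        "seed": cfg.seed,
    }
    return study, eig, manifest
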