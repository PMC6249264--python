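"""Kinship matrices and their spectral decomposition.

A kinship (genetic relatedness) matrix K encodes similarity between
individuals. The standard construction from an n x m column-standardized
genotype matrix Z is the weighted cross-product K = Z W Z^T with a
non-negative diagonal weight per marker (uniform 1/m by default).

Because Z is column-centered, K annihilates the constant vector, so K has
at least one (near-)zero eigenvalue; with fewer markers than individuals K
is low rank. All downstream likelihood work therefore happens in the
subspace spanned by the eigenvectors whose eigenvalues exceed a small
relative threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "GenotypeMatrix",
    "MarkerWeights",
    "Kinship",
    "EigenKinship",
    "standardize_genotypes",
    "build_kinship",
    "eigendecompose",
]

#: relative eigenvalue cutoff: d_i > EIGEN_RTOL * max(d) counts as nonzero
EIGEN_RTOL = 1e-8


@dataclass(frozen=True)
class GenotypeMatrix:
    """Column-standardized dosage matrix (n individuals x m markers)."""

    values: np.ndarray

    def __post_init__(self):
        Z = np.asarray(self.values, dtype=float)
        if Z.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if np.isnan(Z).any():
            raise ValueError("genotype matrix contains missing values; impute first")
        mu = Z.mean(axis=0)
        if np.any(np.abs(mu) > 1e-8):
            raise ValueError("genotype columns are not centered (|mean| > 1e-8)")
        var = Z.var(axis=0)
        if np.any(np.abs(var - 1.0) > 1e-6):
            raise ValueError("genotype columns are not unit-variance (|var-1| > 1e-6)")
        object.__setattr__(self, "values", Z)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MarkerWeights:
    """Non-negative per-marker weights (diagonal of W)."""

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float).ravel()
        if np.any(w < 0):
            raise ValueError("marker weights must be non-negative")
        object.__setattr__(self, "w", w)

    @classmethod
    def uniform(cls, m: int) -> "MarkerWeights":
        return cls(np.full(m, 1.0 / m))


@dataclass(frozen=True)
class Kinship:
    """Symmetric PSD relatedness matrix."""

    values: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        scale = max(np.abs(K).max(), 1.0)
        if np.abs(K - K.T).max() > 1e-10 * scale:
            raise ValueError("kinship matrix is not symmetric")
        object.__setattr__(self, "values", 0.5 * (K + K.T))

    @property
    def n(self) -> int:
        return self.values.shape[0]


def standardize_genotypes(dosages: np.ndarray) -> GenotypeMatrix:
    """Impute missing dosages to the column mean, then center/scale each column.

    Raises on monomorphic columns (zero variance after imputation).
    """
    Z = np.array(dosages, dtype=float)
    if Z.ndim != 2:
        raise ValueError("dosage matrix must be 2-D")
    col_mean = np.nanmean(Z, axis=0)
    nan_idx = np.where(np.isnan(Z))
    Z[nan_idx] = np.take(col_mean, nan_idx[1])
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"monomorphic marker column(s): {bad.tolist()}")
    return GenotypeMatrix((Z - mu) / sd)


def _as_array(x, cls, attr):
    if isinstance(x, cls):
        return getattr(x, attr)
    return np.asarray(x, dtype=float)


def build_kinship(Z, w=None) -> Kinship:
    """K = Z diag(w) Z^T; uniform w = 1/m when no weights are given."""
    Zv = _as_array(Z, GenotypeMatrix, "values")
    m = Zv.shape[1]
    if w is None:
        wv = np.full(m, 1.0 / m)
    else:
        wv = _as_array(w, MarkerWeights, "w").ravel()
    if wv.shape[0] != m:
        raise ValueError(f"got {wv.shape[0]} weights for {m} markers")
    if np.any(wv < 0):
        raise ValueError("marker weights must be non-negative")
    K = (Zv * wv) @ Zv.T
    return Kinship(0.5 * (K + K.T))


@dataclass(frozen=True)
class EigenKinship:
    """Eigendecomposition K = U diag(d) U^T, eigenvalues sorted descending.

    ``z`` counts eigenvalues above ``threshold``; the first z columns of U
    span the subspace used for the projected restricted likelihood.
    """

    U: np.ndarray
    d: np.ndarray
    z: int
    threshold: float

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def U_z(self) -> np.ndarray:
        return self.U[:, : self.z]

    @property
    def d_z(self) -> np.ndarray:
        return self.d[: self.z]

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.d) @ self.U.T


def eigendecompose(K, threshold: float | None = None) -> EigenKinship:
    """Full symmetric eigendecomposition with relative near-zero detection.

    The default threshold is EIGEN_RTOL * max(d): scale-free, so centering
    or low rank is detected regardless of the kinship's overall magnitude.
    """
    Kv = _as_array(K, Kinship, "values")
    scale = max(np.abs(Kv).max(), 1.0)
    if np.abs(Kv - Kv.T).max() > 1e-8 * scale:
        raise ValueError("cannot eigendecompose a non-symmetric matrix")
    d_asc, U_asc = scipy.linalg.eigh(0.5 * (Kv + Kv.T))
    d = d_asc[::-1].copy()
    U = U_asc[:, ::-1].copy()
    dmax = max(d[0], 0.0)
    if d[-1] < -1e-8 * max(dmax, 1.0):
        raise ValueError(
            f"kinship is not PSD: min eigenvalue {d[-1]:.3e} vs max {dmax:.3e}"
        )
    if threshold is None:
        threshold = EIGEN_RTOL * max(dmax, np.finfo(float).tiny)
    elif threshold <= 0:
        raise ValueError("eigenvalue threshold must be positive")
    z = int(np.sum(d > threshold))
    if z == 0:
        raise ValueError("kinship has no eigenvalue above threshold (zero matrix?)")
    return EigenKinship(U=U, d=d, z=z, threshold=float(threshold))
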