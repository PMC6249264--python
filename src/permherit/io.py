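"""Readers and writers for kinship and phenotype files.

Kinship comes in two dialects:

* the GRM binary triad ``<prefix>.grm.bin`` (float32 lower triangle
  including the diagonal, row-major), ``<prefix>.grm.id`` (family and
  individual ID per line) and ``<prefix>.grm.N.bin`` (float32 per-pair
  marker counts) — the convention shared by the mainstream variance-
  component tools;
* a plain whitespace square text matrix, optionally with a sibling
  ``<path>.id`` table.

Phenotype/covariate tables are whitespace-separated with two leading ID
columns (family, individual) and numeric columns after; a header line is
auto-detected. Individuals are aligned to the kinship by (FID, IID);
unmatched rows are dropped with a logged count.
"""

from __future__ import annotations

import hashlib
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import EigenKinship, Kinship, eigendecompose

logger = logging.getLogger("permherit")

__all__ = [
    "read_grm",
    "write_grm",
    "read_phenotypes",
    "align_to_ids",
    "eigendecompose_cached",
]


def _strip_grm_suffix(path: str) -> str:
    for suf in (".grm.bin", ".grm.id", ".grm.N.bin"):
        if str(path).endswith(suf):
            return str(path)[: -len(suf)]
    return str(path)


def write_grm(prefix: str, K: np.ndarray, ids: pd.DataFrame, n_markers: int = 0):
    """Write the binary GRM triad. ``ids`` needs columns FID, IID."""
    K = K.values if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    n = K.shape[0]
    if len(ids) != n:
        raise ValueError(f"{len(ids)} IDs for a {n}x{n} matrix")
    prefix = _strip_grm_suffix(prefix)
    tri = K[np.tril_indices(n)].astype(np.float32)
    tri.tofile(prefix + ".grm.bin")
    np.full(tri.shape, float(n_markers), dtype=np.float32).tofile(prefix + ".grm.N.bin")
    ids.iloc[:, :2].to_csv(prefix + ".grm.id", sep="\t", header=False, index=False)


def _read_grm_binary(prefix: str):
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None,
                      names=["FID", "IID"], dtype=str)
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype=np.float32)
    expected = n * (n + 1) // 2
    if tri.shape[0] != expected:
        raise ValueError(
            f"GRM element count mismatch: {tri.shape[0]} values for n={n} "
            f"IDs (expected n(n+1)/2 = {expected})"
        )
    K = np.zeros((n, n))
    K[np.tril_indices(n)] = tri
    K = K + np.tril(K, -1).T
    return K, ids


def _read_grm_text(path: str):
    K = np.loadtxt(path)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"text kinship at {path} is not square: {K.shape}")
    id_path = str(path) + ".id"
    if os.path.exists(id_path):
        ids = pd.read_csv(id_path, sep=r"\s+", header=None,
                          names=["FID", "IID"], dtype=str)
        if len(ids) != K.shape[0]:
            raise ValueError(
                f"{len(ids)} IDs for a {K.shape[0]}x{K.shape[0]} matrix"
            )
    else:
        ids = pd.DataFrame({
            "FID": [str(i) for i in range(K.shape[0])],
            "IID": [str(i) for i in range(K.shape[0])],
        })
    return K, ids


def read_grm(path: str):
    """Read a kinship matrix, auto-detecting the dialect by extension.

    Returns (K ndarray, ids DataFrame[FID, IID]).
    """
    prefix = _strip_grm_suffix(path)
    if os.path.exists(prefix + ".grm.bin"):
        return _read_grm_binary(prefix)
    if os.path.exists(path):
        return _read_grm_text(path)
    raise FileNotFoundError(f"no kinship found at {path}")


def _detect_header(path: str) -> int | None:
    with open(path) as fh:
        first = fh.readline().split()
    if len(first) < 3:
        return None
    if first[2] in ("NA", "na", "NaN"):
        return None  # missing-value code in a data row: no header
    try:
        float(first[2])
        return None  # third field numeric: no header
    except ValueError:
        return 0


def read_phenotypes(path: str) -> pd.DataFrame:
    """Whitespace table -> DataFrame indexed by (FID, IID), numeric columns.

    'NA' (and blank) cells become NaN; non-numeric cells raise with their
    row/column location.
    """
    header = _detect_header(path)
    df = pd.read_csv(path, sep=r"\s+", header=header, dtype=str,
                     na_values=["NA", "na", "NaN"])
    if df.shape[1] < 3:
        raise ValueError("phenotype table needs two ID columns plus data")
    if header is None:
        df.columns = ["FID", "IID"] + [f"V{i}" for i in range(1, df.shape[1] - 1)]
    else:
        df = df.rename(columns={df.columns[0]: "FID", df.columns[1]: "IID"})
    for col in df.columns[2:]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"non-numeric value in column {col!r}, row {bad.index[0]}"
            ) from None
    df["FID"] = df["FID"].astype(str)
    df["IID"] = df["IID"].astype(str)
    return df.set_index(["FID", "IID"])


def align_to_ids(table: pd.DataFrame, ids: pd.DataFrame):
    """Reorder a (FID, IID)-indexed table to the kinship's ID order.

    Returns (aligned table, integer positions into the kinship). Unmatched
    individuals on either side are dropped and logged; zero overlap is an
    error.
    """
    key = pd.MultiIndex.from_frame(ids[["FID", "IID"]].astype(str))
    present = key.isin(table.index)
    if not present.any():
        raise ValueError("no overlap between kinship IDs and phenotype IDs")
    dropped = int((~present).sum()) + int((~table.index.isin(key)).sum())
    if dropped:
        logger.info("dropped %d unmatched individuals during alignment", dropped)
    positions = np.flatnonzero(present)
    aligned = table.loc[key[present]]
    return aligned, positions


def eigendecompose_cached(K: np.ndarray, cache_dir: str | None = None) -> EigenKinship:
    """Eigendecompose with an on-disk cache keyed by a content hash of K."""
    if cache_dir is None:
        return eigendecompose(K)
    Kv = K.values if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    digest = hashlib.sha256(np.ascontiguousarray(Kv).tobytes()).hexdigest()[:24]
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    f = cache / f"eig_{digest}.npz"
    if f.exists():
        with np.load(f) as npz:
            return EigenKinship(U=npz["U"], d=npz["d"], z=int(npz["z"]),
                                threshold=float(npz["threshold"]))
    eig = eigendecompose(Kv)
    np.savez(f, U=eig.U, d=eig.d, z=eig.z, threshold=eig.threshold)
    return eig
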