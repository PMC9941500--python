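"""Shared matrix helpers: half-vectorization and positive-semidefinite repair.

The half-vectorization convention used throughout the package is the
column-major lower triangle: for a symmetric k x k matrix the unique elements
are ordered (0,0), (1,0), ..., (k-1,0), (1,1), (2,1), ..., (k-1,k-1).
Sampling covariance matrices of genetic covariance estimates are indexed in
this order everywhere.
"""

from __future__ import annotations

import numpy as np


def vech_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the column-major lower triangle of a k x k matrix."""
    rows = np.concatenate([np.arange(j, k) for j in range(k)])
    cols = np.concatenate([np.full(k - j, j) for j in range(k)])
    return rows, cols


def vech(m: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix (column-major lower triangle)."""
    k = m.shape[0]
    r, c = vech_indices(k)
    return np.asarray(m)[r, c]


def unvech(v: np.ndarray, k: int | None = None) -> np.ndarray:
    """Inverse of :func:`vech`: rebuild the full symmetric matrix."""
    v = np.asarray(v)
    if k is None:
        k = int(round((np.sqrt(8 * v.size + 1) - 1) / 2))
    out = np.zeros((k, k), dtype=v.dtype)
    r, c = vech_indices(k)
    out[r, c] = v
    out[c, r] = v
    return out


def nearest_psd(m: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix to the nearest PSD matrix.

    Eigenvalues below ``floor`` are raised to ``floor``; the eigenvectors are
    kept. Already-PSD input is returned bitwise unchanged.
    """
    m = np.asarray(m, dtype=float)
    w, q = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() >= floor:
        return m
    w = np.clip(w, floor, None)
    return (q * w) @ q.T


def cov_to_corr(s: np.ndarray) -> np.ndarray:
    """Convert a covariance matrix to a correlation matrix.

    Raises ``ValueError`` when any diagonal entry is non-positive (for genetic
    covariance matrices this means a non-positive heritability estimate, which
    cannot be standardized).
    """
    d = np.diag(s)
    if np.any(d <= 0):
        bad = np.where(d <= 0)[0].tolist()
        raise ValueError(
            f"cannot standardize: non-positive diagonal entries at indices {bad}"
        )
    inv = 1.0 / np.sqrt(d)
    return s * np.outer(inv, inv)
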