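"""Factor-count decisions and exploratory factor analysis of genetic correlations.

Three non-graphical scree rules decide the number of factors: the Kaiser
rule (eigenvalues strictly greater than one), the acceleration factor (the
position preceding the maximum second difference of the scree), and optimal
coordinates (eigenvalues exceeding the value predicted by a line through the
next eigenvalue and the last one). The EFA is maximum-likelihood factor
extraction on the correlation matrix followed by a varimax rotation and an
oblique promax rotation (power 4), matching the conventional "promax"
correlated-factor rotation. Indicators are then assigned to the factor on
which they load above a threshold, falling back to the largest loading;
indicators qualifying on two or more factors are flagged as cross-loading
(they stay assigned to the largest loading, and the cross-loading is not
carried into confirmatory models).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

_SMOOTH_EIG_FLOOR = 1e-8


@dataclass
class FactorCountDecision:
    kaiser: int
    acceleration_factor: int
    optimal_coordinates: int
    eigenvalues: np.ndarray  # sorted descending


@dataclass
class EFAResult:
    loadings: pd.DataFrame          # k x m rotated pattern matrix
    factor_corr: np.ndarray         # m x m factor correlation matrix
    assignment: dict[str, str]      # indicator -> factor label
    cross_loading_flags: dict[str, dict[str, float]] = field(default_factory=dict)
    uniquenesses: np.ndarray | None = None
    heywood: list[str] = field(default_factory=list)


def _validate_corr(R: np.ndarray | pd.DataFrame, clip: bool = True) -> np.ndarray:
    names = list(R.columns) if isinstance(R, pd.DataFrame) else None
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix contains non-finite entries")
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    if clip and (np.abs(R) > 1).any():
        logger.warning("clipping correlation entries outside [-1, 1] for eigen/EFA use")
        R = np.clip(R, -1.0, 1.0)
        np.fill_diagonal(R, 1.0)
    return R if names is None else pd.DataFrame(R, index=names, columns=names)


def factor_count(R: np.ndarray | pd.DataFrame) -> FactorCountDecision:
    """Apply the Kaiser, acceleration-factor and optimal-coordinates rules."""
    Rm = np.asarray(_validate_corr(R))
    k = Rm.shape[0]
    ev = np.sort(np.linalg.eigvalsh(Rm))[::-1]

    kaiser = int(np.sum(ev > 1.0))

    # acceleration factor: second differences at interior positions 2..k-1
    # (1-indexed); the solution precedes the maximum acceleration.
    if k >= 3:
        accel = ev[2:] - 2.0 * ev[1:-1] + ev[:-2]
        naf = max(1, int(np.argmax(accel)) + 1)  # position i-1 for interior i
    else:
        naf = 1

    # optimal coordinates: predict e_i from the line through (i+1, e_{i+1})
    # and (k, e_k); count eigenvalues exceeding their prediction.
    noc = 0
    for i in range(k - 2):
        slope = (ev[k - 1] - ev[i + 1]) / ((k - 1) - (i + 1))
        pred = ev[i + 1] - slope
        if ev[i] > pred:
            noc += 1
    noc = max(1, noc)

    return FactorCountDecision(
        kaiser=kaiser, acceleration_factor=naf, optimal_coordinates=noc, eigenvalues=ev
    )


# ---------------------------------------------------------------------------
# maximum-likelihood factor extraction (profile likelihood over uniquenesses)
# ---------------------------------------------------------------------------

def _ml_objective(log_psi: np.ndarray, R: np.ndarray, m: int) -> float:
    psi = np.exp(log_psi)
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    ev = np.sort(np.linalg.eigvalsh(Rs))[::-1]
    tail = np.maximum(ev[m:], 1e-12)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _ml_loadings(R: np.ndarray, m: int, psi: np.ndarray) -> np.ndarray:
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    ev, vec = np.linalg.eigh(Rs)
    order = np.argsort(ev)[::-1][:m]
    lam = vec[:, order] * np.sqrt(np.maximum(ev[order] - 1.0, 0.0))
    return lam * np.sqrt(psi)[:, None]


def _smooth(R: np.ndarray) -> np.ndarray:
    w, q = np.linalg.eigh(R)
    if w.min() >= _SMOOTH_EIG_FLOOR:
        return R
    logger.warning(
        "correlation matrix not positive definite (min eigenvalue %.3g); "
        "eigenvalue-clipped at %.0e before ML extraction", w.min(), _SMOOTH_EIG_FLOOR,
    )
    w = np.clip(w, _SMOOTH_EIG_FLOOR, None)
    Rs = (q * w) @ q.T
    d = np.sqrt(np.diag(Rs))
    Rs = Rs / np.outer(d, d)
    return Rs


def _varimax(lam: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser-normalized)."""
    k, m = lam.shape
    if m == 1:
        return lam.copy()
    h = np.sqrt((lam ** 2).sum(axis=1))
    h[h == 0] = 1.0
    A = lam / h[:, None]
    T = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        L = A @ T
        u, s, vt = np.linalg.svd(A.T @ (L ** 3 - L @ np.diag((L ** 2).sum(axis=0)) / k))
        T = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return (A @ T) * h[:, None]


def _promax(lam_varimax: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation on a varimax solution; returns (pattern, Phi)."""
    k, m = lam_varimax.shape
    if m == 1:
        return lam_varimax.copy(), np.eye(1)
    # target: loadings raised to the power, signs preserved
    target = np.abs(lam_varimax) ** power * np.sign(lam_varimax)
    Q, *_ = np.linalg.lstsq(lam_varimax, target, rcond=None)
    # normalize so the implied factors have unit variance
    d = np.diag(np.linalg.inv(Q.T @ Q))
    Q = Q * np.sqrt(d)[None, :]
    pattern = lam_varimax @ Q
    phi = np.linalg.inv(Q.T @ Q)
    d2 = np.sqrt(np.diag(phi))
    phi = phi / np.outer(d2, d2)
    return pattern, phi


def efa(
    R: np.ndarray | pd.DataFrame,
    m: int,
    rotation: str = "promax",
    promax_power: int = 4,
    assign_threshold: float = 0.5,
) -> EFAResult:
    """ML factor analysis of a correlation matrix with promax rotation.

    Deterministic given (R, m): the optimizer start is the squared-multiple-
    correlation communality estimate, and each rotated factor's sign is fixed
    so its largest-magnitude loading is positive.
    """
    names = list(R.columns) if isinstance(R, pd.DataFrame) else None
    Rm = np.asarray(_validate_corr(R))
    k = Rm.shape[0]
    if not (0 < m < k):
        raise ValueError(f"factor count m={m} must lie in (0, {k})")
    if names is None:
        names = [f"V{i + 1}" for i in range(k)]
    Rm = _smooth(Rm)

    # start from squared multiple correlations
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(Rm))
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        _ml_objective, np.log(psi0), args=(Rm, m), method="L-BFGS-B",
        bounds=[(np.log(1e-4), np.log(1.0))] * k,
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
    )
    psi = np.exp(res.x)
    heywood = [names[i] for i in range(k) if psi[i] <= 1.5e-4]
    if heywood:
        warnings.warn(f"Heywood cases (uniqueness at bound): {heywood}", stacklevel=2)
    lam = _ml_loadings(Rm, m, psi)

    if m == 1 or rotation is None or rotation == "none":
        pattern, phi = lam.copy(), np.eye(m)
    elif rotation == "promax":
        pattern, phi = _promax(_varimax(lam), power=promax_power)
    elif rotation == "varimax":
        pattern, phi = _varimax(lam), np.eye(m)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    # sign convention: largest-magnitude loading of each factor positive
    for f in range(pattern.shape[1]):
        j = np.argmax(np.abs(pattern[:, f]))
        if pattern[j, f] < 0:
            pattern[:, f] *= -1
            phi[f, :] *= -1
            phi[:, f] *= -1

    factors = [f"F{f + 1}" for f in range(m)]
    loadings = pd.DataFrame(pattern, index=names, columns=factors)
    assignment, flags = assign(loadings, threshold=assign_threshold)
    return EFAResult(
        loadings=loadings, factor_corr=phi, assignment=assignment,
        cross_loading_flags=flags, uniquenesses=psi, heywood=heywood,
    )


def assign(
    loadings: pd.DataFrame, threshold: float = 0.5
) -> tuple[dict[str, str], dict[str, dict[str, float]]]:
    """Two-step indicator-to-factor assignment.

    An indicator goes to the factor where its loading exceeds ``threshold``;
    if none (or several) qualify it goes to the factor with the largest
    loading. Indicators qualifying on two or more factors are flagged as
    cross-loading with all qualifying loadings recorded; ties on the
    fallback maximum break toward the lower factor index (logged).
    """
    vals = loadings.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("loadings must be finite")
    assignment: dict[str, str] = {}
    flags: dict[str, dict[str, float]] = {}
    for i, ind in enumerate(loadings.index):
        row = vals[i]
        qualifying = np.where(row > threshold)[0]
        best = int(np.argmax(row))  # argmax breaks ties toward lower index
        if (row == row[best]).sum() > 1:
            logger.info("%s: tie on maximum loading broken toward lower factor index", ind)
        assignment[ind] = loadings.columns[best]
        if len(qualifying) >= 2:
            flags[ind] = {loadings.columns[f]: float(row[f]) for f in qualifying}
    return assignment, flags
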