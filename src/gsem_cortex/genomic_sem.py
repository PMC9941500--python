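"""Confirmatory structural modeling on genetic covariance matrices.

Models are fit to the genetic covariance matrix S by diagonally weighted
least squares: the free parameters minimize

    F(theta) = sum_u  (s_u - sigma_u(theta))^2 / V_uu

over the unique (half-vectorized) elements u of S, with V the jackknife
sampling covariance of those elements. Standard errors use the sandwich
correction with the full V, so dependent estimation errors across S's
elements (e.g., from participant overlap) propagate into the SEs. The model
chi-square is the residual-based statistic of Browne (1984), which is
asymptotically chi-square distributed for any consistent weight matrix and
is exactly zero at a perfect fit.

Identification follows the conventions of genomic factor modeling: every
factor has unit variance (variance fixed to 1), a factor with exactly two
indicators carries an equality constraint on its loadings, a factor with a
single indicator has that indicator's residual variance fixed to 0, and in
bifactor models the general factor and all residual factors are mutually
orthogonal.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._linalg import nearest_psd, vech, vech_indices

logger = logging.getLogger(__name__)

_V_EIG_FLOOR = 1e-10

# parameter ids: ("lam", indicator, factor), ("phi", f, g) with f <= g,
# ("theta", i, j) with i <= j  (string labels throughout)


def _pname(pid: tuple) -> str:
    kind = pid[0]
    if kind == "lam":
        return f"{pid[2]}=~{pid[1]}"
    return f"{pid[1]}~~{pid[2]}"


@dataclass
class ModelSpec:
    """A structural model over the indicators of S.

    ``loading_pattern`` maps (factor, indicator) to "free" or a fixed float;
    pairs absent from the mapping are fixed to 0. ``factor_cov`` and
    ``residual_cov``/``residual_var`` follow the same convention, except
    that unspecified residual variances default to free and unspecified
    factor variances are fixed to 1 (unit-variance identification).
    ``equality_groups`` lists sets of parameter names constrained equal.
    """

    indicators: list[str]
    factors: list[str]
    loading_pattern: dict[tuple[str, str], object] = field(default_factory=dict)
    factor_cov: dict[tuple[str, str], object] = field(default_factory=dict)
    residual_cov: set[tuple[str, str]] = field(default_factory=set)
    residual_var: dict[str, object] = field(default_factory=dict)
    equality_groups: list[list[str]] = field(default_factory=list)
    kind: str | None = None  # "common" | "correlated" | "bifactor" | None

    def __post_init__(self):
        for f in self.factors:
            self.factor_cov.setdefault((f, f), 1.0)
        self.residual_cov = {tuple(sorted(p)) for p in self.residual_cov}
        for ind in self.indicators:
            self.residual_var.setdefault(ind, "free")
        self._enforce_identification()

    def _enforce_identification(self) -> None:
        for f in self.factors:
            inds = [i for i in self.indicators if self.loading_pattern.get((f, i)) == "free"]
            if len(inds) == 2:
                grp = [_pname(("lam", i, f)) for i in inds]
                if not any(set(grp) <= set(g) for g in self.equality_groups):
                    self.equality_groups.append(grp)
            elif len(inds) == 1:
                self.residual_var[inds[0]] = 0.0

    # -- parameter bookkeeping -------------------------------------------

    def free_param_ids(self) -> list[tuple]:
        ids: list[tuple] = []
        for f in self.factors:
            for i in self.indicators:
                if self.loading_pattern.get((f, i)) == "free":
                    ids.append(("lam", i, f))
        for a, f in enumerate(self.factors):
            for g in self.factors[a:]:
                if self.factor_cov.get(tuple(sorted((f, g))), 0.0) == "free":
                    ids.append(("phi", *sorted((f, g))))
        for i in self.indicators:
            if self.residual_var.get(i) == "free":
                ids.append(("theta", i, i))
        for (a, b) in sorted(self.residual_cov):
            ids.append(("theta", a, b))
        return ids

    def param_groups(self) -> list[list[tuple]]:
        """Free parameters, merged into equality groups."""
        ids = self.free_param_ids()
        by_name = {_pname(pid): pid for pid in ids}
        grouped: list[list[tuple]] = []
        used: set[str] = set()
        for grp in self.equality_groups:
            members = [by_name[name] for name in grp if name in by_name]
            if members:
                grouped.append(members)
                used.update(_pname(m) for m in members)
        for pid in ids:
            if _pname(pid) not in used:
                grouped.append([pid])
        return grouped

    @property
    def n_free(self) -> int:
        return len(self.param_groups())

    def df(self) -> int:
        k = len(self.indicators)
        return k * (k + 1) // 2 - self.n_free


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    chi2: float
    df: int
    converged: bool
    standardized: dict[str, float]
    sigma: np.ndarray                 # model-implied covariance
    theta_free: np.ndarray = field(repr=False)
    n_free: int = 0
    message: str = ""

    def param_table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            se = self.se.get(name, np.nan)
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {"param": name, "est": est, "se": se, "z": z, "p": p,
                 "std": self.standardized.get(name, np.nan)}
            )
        return pd.DataFrame(rows)


@dataclass
class FitIndices:
    AIC: float
    CFI: float
    SRMR: float
    chi2: float = np.nan
    df: int = 0
    defined: bool = True


@dataclass
class ResidualSearchTrace:
    steps: list[dict] = field(default_factory=list)
    stopped_candidate: dict | None = None
    blacklisted: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_model(assignment: Mapping[str, str], kind: str) -> ModelSpec:
    """Build a common-factor, correlated-factors or bifactor specification.

    ``assignment`` maps each indicator to its (residual-)factor label. The
    identification rules (unit factor variances, two-indicator equality
    constraints, single-indicator fixed residuals, orthogonal residual
    factors in the bifactor) are enforced automatically.
    """
    indicators = list(assignment)
    if not indicators:
        raise ValueError("assignment is empty: every factor needs indicators")
    factor_labels = sorted(set(assignment.values()), key=list(assignment.values()).index)

    if kind == "common":
        name = factor_labels[0] if len(factor_labels) == 1 else "G"
        factors = [name]
        loading = {(name, i): "free" for i in indicators}
        fcov: dict[tuple[str, str], object] = {}
    elif kind == "correlated":
        factors = factor_labels
        loading = {(assignment[i], i): "free" for i in indicators}
        fcov = {
            tuple(sorted((f, g))): "free"
            for a, f in enumerate(factors) for g in factors[a + 1:]
        }
    elif kind == "bifactor":
        factors = ["G"] + factor_labels
        loading = {("G", i): "free" for i in indicators}
        loading.update({(assignment[i], i): "free" for i in indicators})
        fcov = {
            tuple(sorted((f, g))): 0.0
            for a, f in enumerate(factors) for g in factors[a + 1:]
        }
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    spec = ModelSpec(
        indicators=indicators, factors=factors,
        loading_pattern=loading, factor_cov=fcov, kind=kind,
    )
    # single-indicator residual factors in a bifactor: the general loading is
    # also free, so the rule keys on the residual factor's indicator count
    return spec


def independence_model(indicators: Sequence[str]) -> ModelSpec:
    """Null model: all covariances fixed to zero, variances free."""
    return ModelSpec(indicators=list(indicators), factors=[], kind="independence")


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

class _Model:
    """Compiled model: index maps from the free-parameter vector to matrices."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.inds = spec.indicators
        self.facs = spec.factors
        self.k = len(self.inds)
        self.m = len(self.facs)
        self.i_of = {ind: i for i, ind in enumerate(self.inds)}
        self.f_of = {f: i for i, f in enumerate(self.facs)}
        self.groups = spec.param_groups()
        self.names = [_pname(g[0]) for g in self.groups]
        self.member_names = [[_pname(pid) for pid in g] for g in self.groups]

        self.lam_fixed = np.zeros((self.k, self.m))
        self.phi_fixed = np.zeros((self.m, self.m))
        self.theta_fixed = np.zeros((self.k, self.k))
        for (f, i), v in spec.loading_pattern.items():
            if v != "free":
                self.lam_fixed[self.i_of[i], self.f_of[f]] = float(v)
        for (f, g), v in spec.factor_cov.items():
            if v != "free":
                a, b = self.f_of[f], self.f_of[g]
                self.phi_fixed[a, b] = self.phi_fixed[b, a] = float(v)
        for i, v in spec.residual_var.items():
            if v != "free":
                self.theta_fixed[self.i_of[i], self.i_of[i]] = float(v)

        # per group: list of (kind_code, idx1, idx2)
        self.slots: list[list[tuple[int, int, int]]] = []
        for g in self.groups:
            slot = []
            for pid in g:
                if pid[0] == "lam":
                    slot.append((0, self.i_of[pid[1]], self.f_of[pid[2]]))
                elif pid[0] == "phi":
                    slot.append((1, self.f_of[pid[1]], self.f_of[pid[2]]))
                else:
                    slot.append((2, self.i_of[pid[1]], self.i_of[pid[2]]))
            self.slots.append(slot)
        self.q = len(self.groups)
        self.vech_r, self.vech_c = vech_indices(self.k)

    def matrices(self, theta: np.ndarray):
        lam = self.lam_fixed.copy()
        phi = self.phi_fixed.copy()
        th = self.theta_fixed.copy()
        for val, slot in zip(theta, self.slots):
            for code, a, b in slot:
                if code == 0:
                    lam[a, b] = val
                elif code == 1:
                    phi[a, b] = phi[b, a] = val
                else:
                    th[a, b] = th[b, a] = val
        return lam, phi, th

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        lam, phi, th = self.matrices(theta)
        if self.m:
            return lam @ phi @ lam.T + th
        return th

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """d vech(Sigma) / d theta, one column per free parameter group."""
        lam, phi, th = self.matrices(theta)
        pl = (phi @ lam.T) if self.m else None
        J = np.zeros((self.vech_r.size, self.q))
        for gi, slot in enumerate(self.slots):
            dS = np.zeros((self.k, self.k))
            for code, a, b in slot:
                if code == 0:  # loading (a = indicator, b = factor)
                    dS[a, :] += pl[b, :]
                    dS[:, a] += pl[b, :]
                elif code == 1:  # factor covariance
                    la, lb = lam[:, a], lam[:, b]
                    if a == b:
                        dS += np.outer(la, la)
                    else:
                        dS += np.outer(la, lb) + np.outer(lb, la)
                else:  # residual (co)variance
                    if a == b:
                        dS[a, a] += 1.0
                    else:
                        dS[a, b] += 1.0
                        dS[b, a] += 1.0
            J[:, gi] = dS[self.vech_r, self.vech_c]
        return J

    def start(self, S: np.ndarray) -> np.ndarray:
        theta0 = np.empty(self.q)
        diag = np.diag(S)
        for gi, g in enumerate(self.groups):
            pid = g[0]
            if pid[0] == "lam":
                theta0[gi] = 0.5
            elif pid[0] == "phi":
                theta0[gi] = 0.0 if pid[1] != pid[2] else 1.0
            else:
                i = self.i_of[pid[1]]
                theta0[gi] = 0.5 * diag[i] if pid[1] == pid[2] else 0.0
        return theta0


def _prepare_v(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (possibly smoothed) V and the DWLS weight vector 1/diag(V)."""
    V = np.asarray(V, dtype=float)
    V = (V + V.T) / 2.0
    w_eigs = np.linalg.eigvalsh(V)
    if w_eigs.min() < 0:
        pre = V.copy()
        V = nearest_psd(V, floor=_V_EIG_FLOOR)
        dmax = np.max(np.abs(V - pre) / np.sqrt(np.maximum(np.diag(pre), 1e-30))[:, None])
        logger.warning(
            "sampling covariance V not positive definite; eigenvalue-clipped "
            "(max pre/post Z-discrepancy %.3g)", dmax,
        )
    w = 1.0 / np.maximum(np.diag(V), 1e-30)
    return V, w


def fit(
    S: np.ndarray | pd.DataFrame,
    V: np.ndarray,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> FitResult:
    """Fit a model to (S, V) by DWLS with sandwich SEs and residual chi2.

    Non-convergence is reported through ``FitResult.converged`` (with the
    optimizer message), never raised: a model that fails to converge is a
    substantive outcome for constrained model comparisons.
    """
    if isinstance(S, pd.DataFrame):
        S = S.loc[spec.indicators, spec.indicators].to_numpy(dtype=float)
    S = np.asarray(S, dtype=float)
    model = _Model(spec)
    if S.shape != (model.k, model.k):
        raise ValueError("S dimension does not match the model's indicators")
    s = vech(S)
    V, w = _prepare_v(V)
    if V.shape[0] != s.size:
        raise ValueError("V dimension does not match vech(S)")

    def objective(theta):
        r = s - vech(model.sigma(theta))
        return float(r @ (w * r))

    def grad(theta):
        r = s - vech(model.sigma(theta))
        return -2.0 * model.jacobian(theta).T @ (w * r)

    theta0 = model.start(S)
    res = optimize.minimize(
        objective, theta0, jac=grad, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": tol},
    )
    theta = res.x
    sigma = model.sigma(theta)
    converged = bool(res.success) and np.all(np.isfinite(sigma))

    J = model.jacobian(theta)
    r = s - vech(sigma)

    # sandwich SEs: (J'WJ)^-1 J'W V W J (J'WJ)^-1 with W = diag(w)
    se_free = np.full(model.q, np.nan)
    try:
        JW = J * w[:, None]
        bread = np.linalg.inv(JW.T @ J)
        meat = JW.T @ V @ JW
        cov = bread @ meat @ bread
        se_free = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        converged = False

    chi2, df = _residual_chi2(r, J, V, model)
    if not converged:
        logger.warning("model did not converge: %s", res.message)

    estimates, se, std = {}, {}, {}
    dS = np.sqrt(np.maximum(np.diag(S), 1e-30))
    lam, phi, th = model.matrices(theta)
    for gi, members in enumerate(model.member_names):
        for name, pid in zip(members, model.groups[gi]):
            estimates[name] = float(theta[gi])
            se[name] = float(se_free[gi])
            std[name] = _standardize_one(pid, theta[gi], model, dS)
    # include fixed-to-nonzero parameters in the standardized view? only free
    return FitResult(
        spec=spec, estimates=estimates, se=se, chi2=chi2, df=df,
        converged=converged, standardized=std, sigma=sigma,
        theta_free=theta, n_free=model.q, message=str(res.message),
    )


def _standardize_one(pid: tuple, val: float, model: _Model, dS: np.ndarray) -> float:
    """Standardize one estimate to the correlation metric of the observed S."""
    if pid[0] == "lam":
        return float(val / dS[model.i_of[pid[1]]])
    if pid[0] == "phi":
        return float(val)  # unit-variance factors are already standardized
    i, j = model.i_of[pid[1]], model.i_of[pid[2]]
    return float(val / (dS[i] * dS[j]))


def _residual_chi2(r: np.ndarray, J: np.ndarray, V: np.ndarray, model: _Model):
    """Browne's residual-based test statistic with weight matrix V^+."""
    df = model.vech_r.size - model.q
    if df <= 0:
        return 0.0, df
    Vp = np.linalg.pinv(V, rcond=1e-12)
    if model.q:
        JVJ = np.linalg.pinv(J.T @ Vp @ J)
        U = Vp - Vp @ J @ JVJ @ J.T @ Vp
    else:
        U = Vp
    return float(max(r @ U @ r, 0.0)), df


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def cfi(chi2_m: float, df_m: int, chi2_i: float, df_i: int) -> float:
    """Comparative fit index, clamped to [0, 1].

    Guard: when even the independence model fits (chi2_i < df_i) the
    denominator is taken at the small positive floor, giving CFI = 1 for a
    non-worse target model.
    """
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_m - df_m, chi2_i - df_i, 1e-12)
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def srmr(S: np.ndarray, sigma: np.ndarray) -> float:
    """Root mean square of correlation-metric residuals over unique elements."""
    d = np.sqrt(np.maximum(np.diag(S), 1e-30))
    resid = (S - sigma) / np.outer(d, d)
    return float(np.sqrt(np.mean(vech(resid) ** 2)))


def fit_indices(fit_result: FitResult, S: np.ndarray | pd.DataFrame, V: np.ndarray) -> FitIndices:
    """AIC, CFI and SRMR for a converged fit (CFI via an independence fit)."""
    if isinstance(S, pd.DataFrame):
        S = S.loc[fit_result.spec.indicators, fit_result.spec.indicators].to_numpy(dtype=float)
    indep = fit(S, V, independence_model(fit_result.spec.indicators))
    if not (fit_result.converged and indep.converged):
        return FitIndices(AIC=np.nan, CFI=np.nan, SRMR=np.nan, defined=False)
    c = cfi(fit_result.chi2, fit_result.df, indep.chi2, indep.df)
    aic = fit_result.chi2 + 2.0 * fit_result.n_free
    return FitIndices(
        AIC=float(aic), CFI=c, SRMR=srmr(S, fit_result.sigma),
        chi2=fit_result.chi2, df=fit_result.df,
    )


# ---------------------------------------------------------------------------
# residual-covariance search
# ---------------------------------------------------------------------------

def residual_search(
    S: np.ndarray | pd.DataFrame,
    V: np.ndarray,
    spec: ModelSpec,
    alpha: float = 0.01,
    max_steps: int | None = None,
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
) -> tuple[ModelSpec, FitResult, ResidualSearchTrace]:
    """Iteratively free the largest-residual covariance while Wald p < alpha.

    At each step the standardized residual matrix S - Sigma(theta_hat) (on
    the correlation metric) is scanned over candidate indicator pairs; the
    largest-magnitude entry is freed and the model refit. The freed
    parameter is kept when its Wald p-value is below ``alpha``, otherwise
    the search stops (the rejected candidate is recorded in the trace). A
    refit that fails to converge blacklists the candidate and the search
    continues with the next-largest residual.
    """
    if isinstance(S, pd.DataFrame):
        S = S.loc[spec.indicators, spec.indicators].to_numpy(dtype=float)
    current = spec
    result = fit(S, V, current)
    if not result.converged:
        raise RuntimeError("base model did not converge; cannot run residual search")
    trace = ResidualSearchTrace()
    allowed = None if candidate_pairs is None else {tuple(sorted(p)) for p in candidate_pairs}
    d = np.sqrt(np.maximum(np.diag(S), 1e-30))
    names = current.indicators
    n_steps = 0

    while max_steps is None or n_steps < max_steps:
        resid = (S - result.sigma) / np.outer(d, d)
        cands = []
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                pair = (names[a], names[b])
                if pair in current.residual_cov or pair in trace.blacklisted:
                    continue
                if allowed is not None and pair not in allowed:
                    continue
                cands.append((abs(resid[a, b]), pair))
        if not cands:
            break
        cands.sort(reverse=True)

        advanced = False
        for _, pair in cands:
            new_spec = replace(
                current,
                residual_cov=set(current.residual_cov) | {pair},
                loading_pattern=dict(current.loading_pattern),
                factor_cov=dict(current.factor_cov),
                residual_var=dict(current.residual_var),
                equality_groups=[list(g) for g in current.equality_groups],
            )
            new_fit = fit(S, V, new_spec)
            if not new_fit.converged:
                logger.warning("residual search: refit with %s failed; blacklisted", pair)
                trace.blacklisted.append(pair)
                continue
            pname = f"{pair[0]}~~{pair[1]}"
            est, se = new_fit.estimates[pname], new_fit.se[pname]
            p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else 1.0
            fi = fit_indices(new_fit, S, V)
            record = {
                "pair": pair, "estimate": est, "se": se, "p": p,
                "CFI": fi.CFI, "SRMR": fi.SRMR, "AIC": fi.AIC,
            }
            if p < alpha:
                trace.steps.append(record)
                current, result = new_spec, new_fit
                n_steps += 1
                advanced = True
            else:
                trace.stopped_candidate = record
            break  # either kept (continue outer loop) or stopped
        if not advanced:
            break
    return current, result, trace


# ---------------------------------------------------------------------------
# derived quantities and joint models
# ---------------------------------------------------------------------------

def general_factor_share(fit_result: FitResult, general: str = "G") -> tuple[dict[str, float], float]:
    """Per-indicator and average share of genetic variance from the general factor.

    On the standardized (unit-variance) metric the share for an indicator is
    the squared standardized general-factor loading.
    """
    if fit_result.spec.kind != "bifactor":
        raise ValueError("general_factor_share requires a bifactor fit")
    shares = {}
    for ind in fit_result.spec.indicators:
        lam = fit_result.standardized.get(f"{general}=~{ind}")
        if lam is None:
            raise ValueError(f"no general-factor loading for {ind}")
        shares[ind] = float(lam ** 2)
    return shares, float(np.mean(list(shares.values())))


def combine_specs(brain: ModelSpec, external: ModelSpec, correlate: bool = True) -> ModelSpec:
    """Join two measurement models over a block-structured S.

    All cross covariances between brain factors and external factors are
    freed (when ``correlate``); residual structures stay within blocks.
    """
    overlap = set(brain.indicators) & set(external.indicators)
    if overlap:
        raise ValueError(f"indicator labels shared across models: {sorted(overlap)}")
    f_overlap = set(brain.factors) & set(external.factors)
    if f_overlap:
        raise ValueError(f"factor labels shared across models: {sorted(f_overlap)}")
    joint = ModelSpec(
        indicators=brain.indicators + external.indicators,
        factors=brain.factors + external.factors,
        loading_pattern={**brain.loading_pattern, **external.loading_pattern},
        factor_cov={**brain.factor_cov, **external.factor_cov},
        residual_cov=set(brain.residual_cov) | set(external.residual_cov),
        residual_var={**brain.residual_var, **external.residual_var},
        equality_groups=[list(g) for g in brain.equality_groups + external.equality_groups],
        kind="joint",
    )
    for bf in brain.factors:
        for ef in external.factors:
            joint.factor_cov[tuple(sorted((bf, ef)))] = "free" if correlate else 0.0
    return joint


def constrain_cross_correlations(joint: ModelSpec, brain_factors: Sequence[str],
                                 external_factor: str) -> ModelSpec:
    """Equality-constrain all brain-factor correlations with one external factor."""
    spec = replace(
        joint,
        loading_pattern=dict(joint.loading_pattern),
        factor_cov=dict(joint.factor_cov),
        residual_var=dict(joint.residual_var),
        residual_cov=set(joint.residual_cov),
        equality_groups=[list(g) for g in joint.equality_groups],
    )
    grp = [_pname(("phi", *sorted((bf, external_factor)))) for bf in brain_factors]
    spec.equality_groups.append(grp)
    return spec


@dataclass
class JointModelResult:
    fit: FitResult
    factor_correlations: pd.DataFrame
    residual_trace: ResidualSearchTrace
    final_spec: ModelSpec
    bonferroni_threshold: float


def joint_external_model(
    brain_spec: ModelSpec,
    external_spec: ModelSpec,
    S_joint: pd.DataFrame | np.ndarray,
    V_joint: np.ndarray,
    alpha: float = 0.01,
    bonferroni_family: int | None = None,
) -> JointModelResult:
    """Joint fit of brain and external measurement models with free factor
    correlations, extending the residual search to indicator-trait pairs.

    The Bonferroni family defaults to (#brain indicators x #external
    indicators), the number of possible indicator-trait associations.
    """
    joint = combine_specs(brain_spec, external_spec, correlate=True)
    if bonferroni_family is None:
        bonferroni_family = len(brain_spec.indicators) * len(external_spec.indicators)
    threshold = 0.05 / bonferroni_family

    cross_pairs = [
        tuple(sorted((b, e)))
        for b in brain_spec.indicators for e in external_spec.indicators
    ]
    final_spec, final_fit, trace = residual_search(
        S_joint, V_joint, joint, alpha=alpha, candidate_pairs=cross_pairs
    )

    rows = []
    for bf in brain_spec.factors:
        for ef in external_spec.factors:
            name = _pname(("phi", *sorted((bf, ef))))
            est = final_fit.estimates.get(name, np.nan)
            se = final_fit.se.get(name, np.nan)
            z = est / se if se and se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {"brain_factor": bf, "external_factor": ef, "r_g": est, "se": se,
                 "p": p, "significant": bool(np.isfinite(p) and p < threshold)}
            )
    table = pd.DataFrame(rows)
    return JointModelResult(
        fit=final_fit, factor_correlations=table, residual_trace=trace,
        final_spec=final_spec, bonferroni_threshold=threshold,
    )


@dataclass
class OmnibusResult:
    dchi2: float | None
    ddf: int | None
    p: float | None
    constrained_converged: bool


def omnibus_equality_test(fit_free: FitResult, fit_constrained: FitResult) -> OmnibusResult:
    """Chi-square difference test of free vs equality-constrained correlations.

    Non-convergence of the constrained model is a reportable outcome (the
    difference test is then undefined), not an error.
    """
    if fit_constrained.df < fit_free.df:
        raise ValueError("constrained model must be nested in (not larger than) the free model")
    if len(fit_free.spec.indicators) != len(fit_constrained.spec.indicators):
        raise ValueError("fits are not on the same covariance matrix")
    if not fit_constrained.converged:
        warnings.warn("constrained model did not converge; omnibus test undefined", stacklevel=2)
        return OmnibusResult(None, None, None, constrained_converged=False)
    dchi2 = max(fit_constrained.chi2 - fit_free.chi2, 0.0)
    ddf = fit_constrained.df - fit_free.df
    p = float(stats.chi2.sf(dchi2, ddf)) if ddf > 0 else 1.0
    return OmnibusResult(dchi2=float(dchi2), ddf=int(ddf), p=p, constrained_converged=True)


# ---------------------------------------------------------------------------
# model mini-language
# ---------------------------------------------------------------------------

_EQ_RE = re.compile(r'equal\(\s*"([^"]+)"\s*(?:,\s*"([^"]+)"\s*)+\)')


def parse_model(text: str) -> ModelSpec:
    """Parse a small lavaan-style model description.

    Supported lines: ``F1 =~ A + B + C`` (free loadings), ``A ~~ B``
    (free residual covariance between indicators), ``F1 ~~ 0.3*F2`` /
    ``F1 ~~ 0*F2`` (fixed factor covariance), ``F1 ~~ F2`` (free factor
    covariance), and ``equal("F4=~x", "F4=~y")`` equality constraints.
    Factors are whatever appears on the left of ``=~``.
    """
    loadings: dict[tuple[str, str], object] = {}
    factors: list[str] = []
    indicators: list[str] = []
    fcov: dict[tuple[str, str], object] = {}
    rcov: set[tuple[str, str]] = set()
    rvar: dict[str, object] = {}
    equality: list[list[str]] = []

    pending: list[tuple[str, str, object]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _EQ_RE.match(line)
        if m:
            names = re.findall(r'"([^"]+)"', line)
            equality.append(names)
            continue
        if "=~" in line:
            lhs, rhs = (s.strip() for s in line.split("=~", 1))
            if lhs not in factors:
                factors.append(lhs)
            for item in rhs.split("+"):
                item = item.strip()
                if "*" in item:
                    val, ind = item.split("*", 1)
                    loadings[(lhs, ind.strip())] = float(val)
                else:
                    loadings[(lhs, item)] = "free"
                    ind = item
                ind = ind.strip()
                if ind not in indicators:
                    indicators.append(ind)
            continue
        if "~~" in line:
            lhs, rhs = (s.strip() for s in line.split("~~", 1))
            val: object = "free"
            if "*" in rhs:
                v, rhs = rhs.split("*", 1)
                val, rhs = float(v), rhs.strip()
            pending.append((lhs, rhs, val))
            continue
        raise ValueError(f"cannot parse model line: {raw!r}")

    for lhs, rhs, val in pending:
        if lhs in factors or rhs in factors:
            fcov[tuple(sorted((lhs, rhs)))] = val
        elif lhs == rhs:
            rvar[lhs] = val
        else:
            if val != "free":
                raise ValueError("fixed residual covariances between indicators are not supported")
            rcov.add(tuple(sorted((lhs, rhs))))
            for x in (lhs, rhs):
                if x not in indicators:
                    indicators.append(x)

    return ModelSpec(
        indicators=indicators, factors=factors, loading_pattern=loadings,
        factor_cov=fcov, residual_cov=rcov, residual_var=rvar,
        equality_groups=equality,
    )
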