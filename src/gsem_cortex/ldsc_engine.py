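"""Multivariable LD-score regression with a multivariate block jackknife.

Univariate LDSC regresses chi-square statistics on N*l_j/M to estimate SNP
heritability with a free intercept (~1 + confounding). Bivariate LDSC
regresses z1*z2 on sqrt(N1*N2)*l_j/M; its intercept estimates
rho*N_s/sqrt(N1*N2), the phenotypic correlation weighted by proportional
sample overlap, and its slope the genetic covariance. The multivariable
routine runs every univariate and pairwise regression on the common SNP set
and derives the joint sampling covariance V of all unique genetic covariance
elements from a single delete-one-block jackknife, so that V's off-diagonals
capture dependent estimation errors (e.g., participant overlap).

Regression weights follow the standard LDSC heteroskedasticity and
overcounting scheme, 1/(max(l_j,1) * model-implied variance of the
regressand), estimated in two steps: step one fits on the chi2 < 30 subset
to obtain the parameters that define the weights, step two fits the full
SNP set with those weights and a free intercept. Jackknife blocks are
contiguous, equal-SNP-count, in LD-score file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import cov_to_corr, unvech, vech_indices
from .sumstats_io import CleanedSumstats

logger = logging.getLogger(__name__)

_PRED_FLOOR = 0.05  # floor on the model-implied variance entering the weights
_CHI2_STEP1_MAX = 30.0


@dataclass
class LDScores:
    """Per-SNP LD scores: genome-wide column ``L2`` plus per-annotation columns."""

    table: pd.DataFrame  # indexed by SNP id

    def __post_init__(self):
        if "L2" not in self.table.columns:
            raise ValueError("LD-score table must have an L2 column")
        neg = self.table["L2"] < 0
        if neg.any():
            logger.warning("truncating %d negative LD scores to 0", int(neg.sum()))
            self.table = self.table.copy()
            self.table.loc[neg, "L2"] = 0.0

    @property
    def snp_ids(self) -> pd.Index:
        return self.table.index

    @property
    def annotation_names(self) -> list[str]:
        return [c for c in self.table.columns if c != "L2"]

    @classmethod
    def read(cls, path: str | Path) -> "LDScores":
        df = pd.read_csv(path, sep=r"\s+")
        df = df.set_index("SNP")
        return cls(df)

    def write(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationSet:
    """Annotation sizes and pairwise overlap counts for a SNP universe."""

    sizes: dict[str, int]
    overlaps: dict[tuple[str, str], int]
    total_m: int
    genome_annotation: str | None = None  # name of the all-SNP annotation, if any

    def __post_init__(self):
        for c, m in self.sizes.items():
            if not (0 < m <= self.total_m):
                raise ValueError(f"annotation {c}: size {m} outside (0, {self.total_m}]")
        for (c, t), n in list(self.overlaps.items()):
            self.overlaps[(t, c)] = n
        for c, m in self.sizes.items():
            self.overlaps.setdefault((c, c), m)
            if self.overlaps[(c, c)] != m:
                raise ValueError(f"annotation {c}: self-overlap != size")

    def overlap(self, c: str, t: str) -> int:
        try:
            return self.overlaps[(c, t)]
        except KeyError:
            raise KeyError(f"missing overlap entry for annotations ({c}, {t})") from None

    @property
    def names(self) -> list[str]:
        return list(self.sizes)


@dataclass
class OverlapModel:
    """Sample-overlap structure between two GWAS: rho, N_s and confounding a."""

    rho: float = 0.0
    n_shared: float = 0.0
    confound: float = 0.0

    def __post_init__(self):
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")

    def expected_intercept(self, n1: float, n2: float) -> float:
        if self.n_shared > min(n1, n2):
            raise ValueError("N_s cannot exceed min(N_1, N_2)")
        return self.rho * self.n_shared / np.sqrt(n1 * n2) + self.confound


@dataclass
class RegressionFit:
    """One LDSC regression: slope(s), intercept, jackknife SEs and replicates."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_snps: int
    n_blocks: int
    # delete-one-block estimates, rows = blocks, cols = (slope, intercept)
    block_estimates: np.ndarray = field(repr=False)
    # (slope, intercept) of the step-1 fit that defines the regression weights
    weight_params: tuple[float, float] = (0.0, 1.0)


@dataclass
class GeneticCovariancePair:
    """Genetic covariance matrix S with jackknife sampling covariance V.

    V indexes the unique elements of S by the column-major lower-triangle
    half-vectorization (see :mod:`gsem_cortex._linalg`). ``intercepts``
    holds univariate intercepts on the diagonal and cross-trait intercepts
    off-diagonal.
    """

    names: list[str]
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    n_blocks: int
    n_snps: int
    nonpositive_h2: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.names)

    def corr(self, clip: bool = False) -> pd.DataFrame:
        """Genetic correlation matrix (refuses non-positive heritabilities)."""
        r = cov_to_corr(self.S)
        if clip:
            out = np.clip(r, -1.0, 1.0)
            if not np.array_equal(out, r):
                logger.warning("clipped genetic correlations outside [-1, 1]")
            r = out
        return pd.DataFrame(r, index=self.names, columns=self.names)

    def se_matrix(self) -> np.ndarray:
        """Element-wise jackknife SEs of S, as a full symmetric matrix."""
        return unvech(np.sqrt(np.diag(self.V)), self.k)


# ---------------------------------------------------------------------------
# weighted regression with delete-one-block jackknife
# ---------------------------------------------------------------------------

def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on (x, 1); returns (slope, intercept)."""
    X = np.column_stack([x, np.ones_like(x)])
    a = (X * w[:, None]).T @ X
    b = (X * w[:, None]).T @ y
    sol = np.linalg.solve(a, b)
    return float(sol[0]), float(sol[1])


def _wls_jackknife(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int) -> RegressionFit:
    """Full-sample WLS plus delete-one-block jackknife (weights held fixed)."""
    m = x.size
    X = np.column_stack([x, np.ones_like(x)])
    Xw = X * w[:, None]
    a_full = Xw.T @ X
    b_full = Xw.T @ y
    sol = np.linalg.solve(a_full, b_full)

    bounds = _block_bounds(m, n_blocks)
    block_est = np.empty((n_blocks, 2))
    for i in range(n_blocks):
        lo, hi = bounds[i], bounds[i + 1]
        a_b = Xw[lo:hi].T @ X[lo:hi]
        b_b = Xw[lo:hi].T @ y[lo:hi]
        block_est[i] = np.linalg.solve(a_full - a_b, b_full - b_b)
    mean = block_est.mean(axis=0)
    var = (n_blocks - 1) / n_blocks * ((block_est - mean) ** 2).sum(axis=0)
    se = np.sqrt(var)
    return RegressionFit(
        slope=float(sol[0]), intercept=float(sol[1]),
        slope_se=float(se[0]), intercept_se=float(se[1]),
        n_snps=m, n_blocks=n_blocks, block_estimates=block_est,
    )


def _align(ss: CleanedSumstats, snps: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    sub = ss.table.loc[snps]
    z = sub["Z"].to_numpy(dtype=float)
    n = sub["N"].to_numpy(dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-statistics; filter upstream with munge()")
    return z, n


def _shared_snps(ld: LDScores, *traits: CleanedSumstats) -> pd.Index:
    """Common SNPs of all traits, in LD-score file order (defines the blocks)."""
    mask = np.ones(len(ld.table), dtype=bool)
    for t in traits:
        mask &= ld.snp_ids.isin(t.snp_ids)
    return ld.snp_ids[mask]


def _uni_weights(l2: np.ndarray, n: np.ndarray, m_ref: float, h2: float, a: float) -> np.ndarray:
    h2w = float(np.clip(h2, 0.0, 1.0))
    pred = np.maximum(h2w * n * l2 / m_ref + max(a, 0.1), _PRED_FLOOR)
    return 1.0 / (np.maximum(l2, 1.0) * 2.0 * pred ** 2)


def univariate_ldsc(
    ss: CleanedSumstats,
    ld: LDScores,
    n_blocks: int = 200,
    m_ref: float | None = None,
) -> RegressionFit:
    """Univariate LDSC: chi2_j on N*l_j/M with a free intercept.

    ``m_ref`` is the SNP count M of the regression universe; it defaults to
    the number of shared SNPs. Heritability is reported on the observed
    scale; the slope of the regression is h2 directly.
    """
    snps = _shared_snps(ld, ss)
    if len(snps) < n_blocks:
        raise ValueError(f"{len(snps)} SNPs shared is fewer than {n_blocks} blocks")
    z, n = _align(ss, snps)
    l2 = ld.table.loc[snps, "L2"].to_numpy(dtype=float)
    M = float(m_ref if m_ref is not None else len(snps))

    chi2 = z ** 2
    x = n * l2 / M

    # step 1: parameters defining the weights, on the chi2 < 30 subset
    sub = chi2 < _CHI2_STEP1_MAX
    if sub.sum() < 10:
        sub = np.ones_like(sub)
    denom = float(np.mean(n[sub] * l2[sub])) or 1.0
    h2_0 = float(np.clip((chi2[sub].mean() - 1.0) * M / denom, -1.0, 1.0))
    slope1, int1 = _wls(x[sub], chi2[sub], _uni_weights(l2[sub], n[sub], M, h2_0, 1.0))
    slope1, int1 = _wls(x[sub], chi2[sub], _uni_weights(l2[sub], n[sub], M, slope1, int1))

    # step 2: full SNP set with fixed weights, free intercept, jackknife
    w = _uni_weights(l2, n, M, slope1, int1)
    out = _wls_jackknife(x, chi2, w, n_blocks)
    out.weight_params = (slope1, int1)
    return out


def _biv_weights(
    l2: np.ndarray, n1: np.ndarray, n2: np.ndarray, m_ref: float,
    uni1: RegressionFit, uni2: RegressionFit, cov_slope: float, icept: float,
) -> np.ndarray:
    v1 = np.maximum(np.clip(uni1.slope, 0, 1) * n1 * l2 / m_ref + max(uni1.intercept, 0.1), _PRED_FLOOR)
    v2 = np.maximum(np.clip(uni2.slope, 0, 1) * n2 * l2 / m_ref + max(uni2.intercept, 0.1), _PRED_FLOOR)
    c = cov_slope * np.sqrt(n1 * n2) * l2 / m_ref + icept
    return 1.0 / (np.maximum(l2, 1.0) * (v1 * v2 + c ** 2))


def bivariate_ldsc(
    ss1: CleanedSumstats,
    ss2: CleanedSumstats,
    ld: LDScores,
    n_blocks: int = 200,
    m_ref: float | None = None,
    _uni: tuple[RegressionFit, RegressionFit] | None = None,
) -> RegressionFit:
    """Bivariate LDSC: z1*z2 on sqrt(N1*N2)*l_j/M with a free intercept.

    The slope estimates the genetic covariance; the intercept estimates
    rho*N_s/sqrt(N1*N2) + shared confounding.
    """
    snps = _shared_snps(ld, ss1, ss2)
    if len(snps) < n_blocks:
        raise ValueError(f"{len(snps)} SNPs shared is fewer than {n_blocks} blocks")
    z1, n1 = _align(ss1, snps)
    z2, n2 = _align(ss2, snps)
    l2 = ld.table.loc[snps, "L2"].to_numpy(dtype=float)
    M = float(m_ref if m_ref is not None else len(snps))

    if _uni is None:
        uni1 = univariate_ldsc(ss1, ld, n_blocks=n_blocks, m_ref=m_ref)
        uni2 = univariate_ldsc(ss2, ld, n_blocks=n_blocks, m_ref=m_ref)
    else:
        uni1, uni2 = _uni

    y = z1 * z2
    x = np.sqrt(n1 * n2) * l2 / M

    sub = (z1 ** 2 < _CHI2_STEP1_MAX) & (z2 ** 2 < _CHI2_STEP1_MAX)
    if sub.sum() < 10:
        sub = np.ones_like(sub)
    w0 = _biv_weights(l2[sub], n1[sub], n2[sub], M, uni1, uni2, 0.0, 0.0)
    slope1, int1 = _wls(x[sub], y[sub], w0)
    w1 = _biv_weights(l2[sub], n1[sub], n2[sub], M, uni1, uni2, slope1, int1)
    slope1, int1 = _wls(x[sub], y[sub], w1)

    w = _biv_weights(l2, n1, n2, M, uni1, uni2, slope1, int1)
    out = _wls_jackknife(x, y, w, n_blocks)
    out.weight_params = (slope1, int1)
    return out


def multivariable_ldsc(
    traits: Sequence[CleanedSumstats],
    ld: LDScores,
    n_blocks: int = 200,
    m_ref: float | None = None,
    liability: bool = True,
) -> GeneticCovariancePair:
    """Full (S, V) pair over k traits from one multivariate block jackknife.

    All univariate and bivariate regressions run on the common SNP
    intersection, so every fit shares the same block partition; V is the
    jackknife covariance of the delete-one-block replicates of all
    k(k+1)/2 unique S elements jointly.

    With ``liability=True``, heritabilities of binary traits that carry a
    population prevalence are rescaled to the liability scale (sample
    prevalence defaults to 0.5, the convention when effective sample sizes
    are used); covariances scale by the geometric mean of the per-trait
    multipliers. Intercepts are left on the observed scale.
    """
    k = len(traits)
    if k < 2:
        raise ValueError("need at least two traits")
    names = [t.trait.name for t in traits]
    snps = _shared_snps(ld, *traits)
    if len(snps) < n_blocks:
        raise ValueError(f"{len(snps)} SNPs shared is fewer than {n_blocks} blocks")

    # restrict every trait to the common set so all fits share the blocks
    common = [
        CleanedSumstats(trait=t.trait, table=t.table.loc[snps], filter_log=t.filter_log)
        for t in traits
    ]
    unis = [univariate_ldsc(t, ld, n_blocks=n_blocks, m_ref=m_ref) for t in common]

    S = np.zeros((k, k))
    icept = np.zeros((k, k))
    rows, cols = vech_indices(k)
    n_unique = len(rows)
    blocks = np.zeros((n_blocks, n_unique))

    pair_fits: dict[tuple[int, int], RegressionFit] = {}
    for idx, (i, j) in enumerate(zip(rows, cols)):
        if i == j:
            fit = unis[i]
        else:
            fit = bivariate_ldsc(
                common[i], common[j], ld, n_blocks=n_blocks, m_ref=m_ref,
                _uni=(unis[i], unis[j]),
            )
            pair_fits[(i, j)] = fit
        S[i, j] = S[j, i] = fit.slope
        icept[i, j] = icept[j, i] = fit.intercept
        blocks[:, idx] = fit.block_estimates[:, 0]

    scale = np.ones(k)
    if liability:
        for i, t in enumerate(traits):
            meta = t.trait
            if meta.measurement == "binary" and meta.pop_prev is not None:
                p = meta.sample_prev if meta.sample_prev is not None else 0.5
                scale[i] = liability_multiplier(p, meta.pop_prev)
    g = np.sqrt(scale)
    S = S * np.outer(g, g)
    blocks = blocks * (g[rows] * g[cols])[None, :]

    mean = blocks.mean(axis=0)
    centered = blocks - mean
    V = (n_blocks - 1) / n_blocks * centered.T @ centered

    nonpos = [names[i] for i in range(k) if S[i, i] <= 0]
    for name in nonpos:
        logger.warning("trait %s: non-positive estimated heritability", name)

    return GeneticCovariancePair(
        names=names, S=S, V=V, intercepts=icept,
        n_blocks=n_blocks, n_snps=len(snps), nonpositive_h2=nonpos,
    )


# ---------------------------------------------------------------------------
# liability conversion
# ---------------------------------------------------------------------------

def liability_multiplier(sample_prev: float, pop_prev: float) -> float:
    """Observed-to-liability scale multiplier for h2 of a binary trait.

    K^2 (1-K)^2 / (P(1-P) * phi(tau_K)^2), with tau_K the standard-normal
    quantile at 1-K and phi the standard-normal density.
    """
    p, k = sample_prev, pop_prev
    if not (0 < p < 1) or not (0 < k < 1):
        raise ValueError("prevalences must lie in (0, 1)")
    tau = stats.norm.ppf(1.0 - k)
    phi = stats.norm.pdf(tau)
    return k ** 2 * (1 - k) ** 2 / (p * (1 - p) * phi ** 2)


def liability_transform(h2_obs: float, sample_prev: float, pop_prev: float) -> float:
    """Convert an observed-scale h2 to the liability scale."""
    return h2_obs * liability_multiplier(sample_prev, pop_prev)
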