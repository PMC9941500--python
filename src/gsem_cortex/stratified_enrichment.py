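"""Stratified multivariable LDSC and functional enrichment of factor variances.

The stratified regression jointly models per-annotation coefficients: for a
trait pair the expected z-score product at SNP j is

    E[z1j z2j] = sqrt(N1 N2) * sum_c tau_c * l(j,c)/M_c  + rho*N_s/sqrt(N1 N2) + a

where tau_c is the per-annotation co-heritability controlling for overlap
with the other annotations. Zero-order stratified covariances for a target
annotation t, which do not control for overlap, are recovered as the
overlap-weighted sum

    zeta_t = sum_c (|M_c \\cap M_t| / |M_c|) * tau_c ,

applied element-wise to the k x k tau matrices, with jackknife sampling
covariance propagated through the same linear combination of delete-one-
block replicates. Each zeta_t is screened by eigenvalue-clipping to the
nearest PSD matrix and dropping annotations whose smoothing moves any
element by more than 1.96 standard errors.

Enrichment of a factor variance in annotation t fixes the factor loadings
at the genome-wide model's estimates, frees the factor and residual
variances, refits on (zeta_t, V_t), and divides the estimated factor
variance (and its SE) by the proportional annotation size M_t/M. The
one-tailed p-value tests departure of the enrichment ratio above its null
value of 1; the ratio of the estimate over its SE is also reported as an
alternative column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import nearest_psd, unvech, vech_indices
from .genomic_sem import FitResult, ModelSpec, fit
from .ldsc_engine import AnnotationSet, LDScores, _align, _biv_weights, \
    _block_bounds, _shared_snps, _uni_weights, univariate_ldsc
from .sumstats_io import CleanedSumstats

logger = logging.getLogger(__name__)


@dataclass
class TauMatrixSet:
    """Per-annotation tau coefficient matrices with jackknife replicates.

    ``taus[c]`` is the k x k matrix of tau_c coefficients; ``replicates``
    has shape (n_blocks, n_annotations, k(k+1)/2) and holds the delete-one-
    block estimates in half-vectorization order, shared across annotations
    so linear combinations (e.g., the zero-order conversion) propagate the
    jackknife exactly.
    """

    trait_names: list[str]
    annotation_names: list[str]
    taus: dict[str, np.ndarray]
    intercepts: np.ndarray
    replicates: np.ndarray = field(repr=False)
    n_blocks: int = 0

    @property
    def k(self) -> int:
        return len(self.trait_names)

    def sampling_cov(self, annotation: str) -> np.ndarray:
        idx = self.annotation_names.index(annotation)
        reps = self.replicates[:, idx, :]
        centered = reps - reps.mean(axis=0)
        return (self.n_blocks - 1) / self.n_blocks * centered.T @ centered


@dataclass
class ZeroOrderCovariance:
    """Zero-order stratified genetic covariance for one target annotation."""

    annotation: str
    zeta: np.ndarray
    V: np.ndarray
    screened: bool = False
    max_z_discrepancy: float = 0.0
    retained: bool = True

    def se_matrix(self) -> np.ndarray:
        return unvech(np.sqrt(np.maximum(np.diag(self.V), 0.0)), self.zeta.shape[0])


@dataclass
class EnrichmentEstimate:
    factor: str
    annotation: str
    enrichment: float
    se: float
    p_one_tailed: float          # upper tail of (enrichment - 1) / SE
    p_est_over_se: float         # upper tail of enrichment / SE
    converged: bool = True


def stratified_ldsc(
    traits: Sequence[CleanedSumstats],
    ld: LDScores,
    annotations: AnnotationSet,
    n_blocks: int = 200,
) -> TauMatrixSet:
    """Joint regression of z1*z2 on all annotation LD scores per trait pair.

    Weights come from the genome-wide (column ``L2``) univariate models, as
    in the unstratified engine. Raises when the annotation design matrix is
    rank deficient, naming the collinear annotations.
    """
    k = len(traits)
    names = [t.trait.name for t in traits]
    ann_names = [c for c in annotations.names if c in ld.table.columns]
    snps = _shared_snps(ld, *traits)
    if len(snps) < n_blocks:
        raise ValueError(f"{len(snps)} SNPs shared is fewer than {n_blocks} blocks")
    common = [
        CleanedSumstats(trait=t.trait, table=t.table.loc[snps], filter_log=t.filter_log)
        for t in traits
    ]
    zs, ns = zip(*(_align(t, snps) for t in common))
    l2 = ld.table.loc[snps, "L2"].to_numpy(dtype=float)
    lstrat = ld.table.loc[snps, ann_names].to_numpy(dtype=float)
    m_sizes = np.array([annotations.sizes[c] for c in ann_names], dtype=float)
    M = float(annotations.total_m)

    base = lstrat / m_sizes[None, :]  # l(j,c)/M_c per column
    rank = np.linalg.matrix_rank(base)
    if rank < base.shape[1]:
        # identify collinear columns via QR pivoting on the design
        _, r = np.linalg.qr(base)
        bad = [ann_names[i] for i in range(len(ann_names)) if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
        raise ValueError(f"annotation design is rank deficient; collinear annotations: {bad}")

    unis = [univariate_ldsc(t, ld, n_blocks=n_blocks, m_ref=M) for t in common]

    rows, cols = vech_indices(k)
    n_pairs = len(rows)
    n_ann = len(ann_names)
    taus = np.zeros((n_ann, n_pairs))
    icepts = np.zeros((k, k))
    reps = np.zeros((n_blocks, n_ann, n_pairs))
    bounds = _block_bounds(len(snps), n_blocks)

    for idx, (i, j) in enumerate(zip(rows, cols)):
        if i == j:
            y = zs[i] ** 2
            scale = ns[i]
            w = _uni_weights(l2, ns[i], M, *unis[i].weight_params)
        else:
            y = zs[i] * zs[j]
            scale = np.sqrt(ns[i] * ns[j])
            # two-step weights as in the genome-wide bivariate engine: a
            # preliminary genome-wide product regression sets the covariance
            # term of the weight model
            w0 = _biv_weights(l2, ns[i], ns[j], M, unis[i], unis[j], 0.0, 0.0)
            x_gw = scale * l2 / M
            Xg = np.column_stack([x_gw, np.ones(len(snps))])
            ag = (Xg * w0[:, None]).T @ Xg
            bg = (Xg * w0[:, None]).T @ y
            cov1, int1 = np.linalg.solve(ag, bg)
            w = _biv_weights(l2, ns[i], ns[j], M, unis[i], unis[j], cov1, int1)
        X = np.column_stack([scale[:, None] * base, np.ones(len(snps))])
        Xw = X * w[:, None]
        a_full = Xw.T @ X
        b_full = Xw.T @ y
        sol = np.linalg.solve(a_full, b_full)
        taus[:, idx] = sol[:-1]
        icepts[i, j] = icepts[j, i] = sol[-1]
        for bnum in range(n_blocks):
            lo, hi = bounds[bnum], bounds[bnum + 1]
            a_b = Xw[lo:hi].T @ X[lo:hi]
            b_b = Xw[lo:hi].T @ y[lo:hi]
            reps[bnum, :, idx] = np.linalg.solve(a_full - a_b, b_full - b_b)[:-1]

    tau_mats = {c: unvech(taus[ci], k) for ci, c in enumerate(ann_names)}
    return TauMatrixSet(
        trait_names=names, annotation_names=ann_names, taus=tau_mats,
        intercepts=icepts, replicates=reps, n_blocks=n_blocks,
    )


def zero_order(
    tau_set: TauMatrixSet,
    annotations: AnnotationSet,
    targets: Sequence[str] | None = None,
) -> dict[str, ZeroOrderCovariance]:
    """Convert tau matrices to zero-order stratified covariances (element-wise).

    ``targets`` may include annotations that were not regression columns
    (e.g., the whole-genome annotation) as long as overlap counts with every
    regression annotation are available.
    """
    if targets is None:
        targets = annotations.names
    k = tau_set.k
    nb = tau_set.n_blocks
    out: dict[str, ZeroOrderCovariance] = {}
    for t in targets:
        weights = np.array(
            [annotations.overlap(c, t) / annotations.sizes[c] for c in tau_set.annotation_names]
        )
        zeta = sum(
            w * tau_set.taus[c] for w, c in zip(weights, tau_set.annotation_names)
        )
        reps_t = np.einsum("c,bcp->bp", weights, tau_set.replicates)
        centered = reps_t - reps_t.mean(axis=0)
        V_t = (nb - 1) / nb * centered.T @ centered
        out[t] = ZeroOrderCovariance(annotation=t, zeta=np.asarray(zeta), V=V_t)
    return out


def screen_and_smooth(
    zero_order_set: Mapping[str, ZeroOrderCovariance],
    z_crit: float = 1.96,
) -> dict[str, ZeroOrderCovariance]:
    """Eigen-clip each zeta to PSD and drop annotations that move too much.

    The per-element Z-discrepancy is |pre - post| / SE; an annotation is
    excluded when any element exceeds ``z_crit``. Exclusions are logged.
    """
    out: dict[str, ZeroOrderCovariance] = {}
    for name, zo in zero_order_set.items():
        smoothed = nearest_psd(zo.zeta, floor=0.0)
        se = zo.se_matrix()
        with np.errstate(divide="ignore", invalid="ignore"):
            disc = np.abs(zo.zeta - smoothed) / np.where(se > 0, se, np.inf)
        max_disc = float(np.nanmax(disc)) if disc.size else 0.0
        retained = max_disc <= z_crit
        if not retained:
            logger.warning(
                "annotation %s excluded: smoothing Z-discrepancy %.2f > %.2f",
                name, max_disc, z_crit,
            )
        out[name] = replace(
            zo, zeta=smoothed, screened=True,
            max_z_discrepancy=max_disc, retained=retained,
        )
    return out


def _fixed_loading_spec(genomewide_fit: FitResult) -> ModelSpec:
    """Spec with loadings fixed at the genome-wide estimates, variances free."""
    base = genomewide_fit.spec
    loading: dict[tuple[str, str], object] = {}
    for key, v in base.loading_pattern.items():
        if v == "free":
            loading[key] = genomewide_fit.estimates[f"{key[0]}=~{key[1]}"]
        else:
            loading[key] = v
    fcov = dict(base.factor_cov)
    for f in base.factors:
        fcov[(f, f)] = "free"
    rvar = {i: "free" for i in base.indicators}
    for i, v in base.residual_var.items():
        if v != "free":
            rvar[i] = v
    return ModelSpec(
        indicators=list(base.indicators), factors=list(base.factors),
        loading_pattern=loading, factor_cov=fcov,
        residual_cov=set(base.residual_cov), residual_var=rvar,
        equality_groups=[], kind=base.kind,
    )


def factor_enrichment(
    genomewide_fit: FitResult,
    screened: Mapping[str, ZeroOrderCovariance],
    annotations: AnnotationSet,
    report_annotations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Enrichment of every factor variance in every retained annotation.

    With unit-variance identification the genome-wide factor variances are
    1, so enrichment is the annotation-specific factor variance divided by
    M_t/M; the whole-genome annotation is definitionally 1 (its zeta is the
    total genetic covariance refit against itself). Non-converging
    annotation fits are reported as missing rows (NaN estimates).
    """
    if not genomewide_fit.converged:
        raise ValueError("genome-wide model must have converged")
    spec = _fixed_loading_spec(genomewide_fit)
    M = float(annotations.total_m)
    if report_annotations is None:
        report_annotations = [a for a in screened if screened[a].retained]

    rows = []
    for ann in report_annotations:
        zo = screened[ann]
        if not zo.retained:
            continue
        prop = annotations.sizes[ann] / M
        is_genome = (
            ann == annotations.genome_annotation or annotations.sizes[ann] == annotations.total_m
        )
        ann_fit = fit(zo.zeta, zo.V, spec)
        for f in spec.factors:
            name = f"{f}~~{f}"
            if not ann_fit.converged:
                rows.append(EnrichmentEstimate(f, ann, np.nan, np.nan, np.nan, np.nan, False))
                logger.warning("annotation %s: model fit did not converge", ann)
                continue
            var = ann_fit.estimates[name]
            se = ann_fit.se[name]
            enr = 1.0 if is_genome else var / prop
            enr_se = se / prop
            z1 = (enr - 1.0) / enr_se if enr_se > 0 else np.nan
            z2 = enr / enr_se if enr_se > 0 else np.nan
            rows.append(
                EnrichmentEstimate(
                    factor=f, annotation=ann, enrichment=float(enr), se=float(enr_se),
                    p_one_tailed=float(stats.norm.sf(z1)),
                    p_est_over_se=float(stats.norm.sf(z2)),
                )
            )
    return pd.DataFrame([vars(r) for r in rows])


def bonferroni_threshold(n_annotations: int, n_factors: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (annotations x factors)."""
    return alpha / (n_annotations * n_factors)
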