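"""Synthetic multi-trait GWAS studies with known genetic architecture.

The generator works at the z-statistic level: for SNP j the k-vector of
z-statistics across traits is multivariate normal with covariance

    Sigma_j[i,i']  = sqrt(N_i N_i') * sum_c tau_c[i,i'] * l(j,c)/M_c
                     + delta_ii' + rho_ii' N_s,ii' / sqrt(N_i N_i') + a_ii'

— exactly the second-moment structure LD-score regression consumes, so the
generator and the estimator are inverses in expectation. LD enters only
through the (stratified) LD scores; draws are independent across SNPs,
the standard LDSC design approximation. The per-annotation tau matrices
derive from a user-specified factor model: standardized loadings and factor
correlations imply a genetic correlation matrix, heritabilities scale it to
the genetic covariance S, and each annotation's variance share splits S
into tau_c = share_c * S.

Every study carries a TruthRecord holding the generating parameters and the
derived targets (true S, true per-annotation enrichment, expected
intercepts), sufficient to recompute any expected estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ldsc_engine import AnnotationSet, LDScores
from .sumstats_io import CleanedSumstats, TraitMeta

GENOME_ANNOTATION = "base"


@dataclass
class AnnotationDef:
    """One synthetic annotation: its SNP share and its genetic-variance share."""

    name: str
    snp_fraction: float
    variance_share: float


@dataclass
class GenerativeSpec:
    """Ground-truth parameters of a synthetic multi-trait study.

    ``loadings`` are standardized (correlation-metric) factor loadings,
    k x m; ``factor_corr`` the m x m factor correlation matrix. Per-trait
    ``h2`` scales the implied genetic correlation matrix to the genetic
    covariance. ``overlap`` maps trait index pairs (i, j) to (rho, N_s);
    ``confound`` maps pairs (i, j), including (i, i), to the constant a.
    ``annotations`` is a disjoint partition of the genome; the variance
    shares must sum to 1.
    """

    loadings: np.ndarray
    h2: np.ndarray
    factor_corr: np.ndarray | None = None
    M: int = 20_000
    N: np.ndarray | float = 20_000.0
    overlap: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    confound: dict[tuple[int, int], float] = field(default_factory=dict)
    annotations: list[AnnotationDef] = field(default_factory=list)
    residual_corr: dict[tuple[int, int], float] = field(default_factory=dict)
    ld_n_blocks: int = 100
    ld_gamma: tuple[float, float] = (6.0, 8.0)
    seed: int = 0
    trait_names: list[str] | None = None

    def __post_init__(self):
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.h2 = np.asarray(self.h2, dtype=float)
        if self.factor_corr is None:
            self.factor_corr = np.eye(self.loadings.shape[1])
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        if np.isscalar(self.N):
            self.N = np.full(self.k, float(self.N))
        self.N = np.asarray(self.N, dtype=float)
        if not self.annotations:
            self.annotations = [AnnotationDef(GENOME_ANNOTATION, 1.0, 1.0)]
        if not np.isclose(sum(a.snp_fraction for a in self.annotations), 1.0):
            raise ValueError("annotation SNP fractions must partition the genome (sum to 1)")
        if not np.isclose(sum(a.variance_share for a in self.annotations), 1.0):
            raise ValueError("annotation variance shares must sum to 1")
        if np.any(self.h2 <= 0) or np.any(self.h2 >= 1):
            raise ValueError("heritabilities must lie in (0, 1)")
        for (i, j), (rho, ns) in self.overlap.items():
            if ns > min(self.N[i], self.N[j]):
                raise ValueError(f"overlap N_s for pair {(i, j)} exceeds min(N_i, N_j)")
            if abs(rho) > 1:
                raise ValueError("|rho| must be <= 1")
        if self.trait_names is None:
            self.trait_names = [f"trait{i + 1}" for i in range(self.k)]

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    @property
    def genetic_corr(self) -> np.ndarray:
        common = self.loadings @ self.factor_corr @ self.loadings.T
        u = 1.0 - np.diag(common)
        if np.any(u < -1e-10):
            raise ValueError("loadings imply communalities above 1")
        r = common + np.diag(np.clip(u, 0.0, None))
        for (i, j), rc in self.residual_corr.items():
            r[i, j] += rc
            r[j, i] += rc
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValueError("implied genetic correlation matrix is not PSD")
        return r

    @property
    def S_true(self) -> np.ndarray:
        g = np.sqrt(self.h2)
        return self.genetic_corr * np.outer(g, g)

    def tau_true(self) -> dict[str, np.ndarray]:
        return {a.name: a.variance_share * self.S_true for a in self.annotations}

    def intercept_true(self) -> np.ndarray:
        b = np.eye(self.k)
        for (i, j), (rho, ns) in self.overlap.items():
            b[i, j] = b[j, i] = b[i, j] + rho * ns / np.sqrt(self.N[i] * self.N[j])
        for (i, j), a in self.confound.items():
            b[i, j] += a
            if i != j:
                b[j, i] += a
        return b

    def enrichment_true(self) -> dict[str, float]:
        return {a.name: a.variance_share / a.snp_fraction for a in self.annotations}

    @classmethod
    def two_factor(
        cls, k: int = 6, h2: float = 0.3, loading: float = 0.7,
        factor_r: float = 0.4, M: int = 20_000, N: float = 20_000.0,
        seed: int = 0, **kwargs,
    ) -> "GenerativeSpec":
        """The reference two-factor study: k traits split over two correlated
        factors with equal standardized loadings."""
        half = k // 2
        lam = np.zeros((k, 2))
        lam[:half, 0] = loading
        lam[half:, 1] = loading
        phi = np.array([[1.0, factor_r], [factor_r, 1.0]])
        return cls(loadings=lam, h2=np.full(k, h2), factor_corr=phi,
                   M=M, N=N, seed=seed, **kwargs)


@dataclass
class TruthRecord:
    """Serializable record of generating parameters and derived targets."""

    params: dict

    @classmethod
    def from_spec(cls, spec: GenerativeSpec) -> "TruthRecord":
        return cls(params={
            "k": spec.k,
            "M": spec.M,
            "N": spec.N.tolist(),
            "h2": spec.h2.tolist(),
            "loadings": spec.loadings.tolist(),
            "factor_corr": spec.factor_corr.tolist(),
            "overlap": {f"{i},{j}": [rho, ns] for (i, j), (rho, ns) in spec.overlap.items()},
            "confound": {f"{i},{j}": a for (i, j), a in spec.confound.items()},
            "residual_corr": {f"{i},{j}": r for (i, j), r in spec.residual_corr.items()},
            "annotations": [
                {"name": a.name, "snp_fraction": a.snp_fraction,
                 "variance_share": a.variance_share}
                for a in spec.annotations
            ],
            "seed": spec.seed,
            "trait_names": list(spec.trait_names),
            "S_true": spec.S_true.tolist(),
            "genetic_corr": spec.genetic_corr.tolist(),
            "intercepts_true": spec.intercept_true().tolist(),
            "enrichment_true": spec.enrichment_true(),
        })

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.params, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthRecord":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(params=json.loads(text))

    @property
    def S_true(self) -> np.ndarray:
        return np.asarray(self.params["S_true"])


def make_ld_scores(
    M: int,
    annotations: Sequence[AnnotationDef],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_blocks: int = 100,
    gamma: tuple[float, float] = (6.0, 8.0),
) -> tuple[LDScores, AnnotationSet, np.ndarray]:
    """Draw per-SNP LD scores with block structure and annotation membership.

    Genome-wide scores are 1 plus a block-level gamma mean times per-SNP
    right-skewed noise (contiguous blocks share a mean, supporting the
    block jackknife). Each SNP belongs to exactly one annotation of the
    disjoint partition; its stratified score equals its genome-wide score
    within its own annotation and 0 elsewhere, so stratified scores sum to
    the genome-wide score. Returns (scores, annotation set incl. the
    whole-genome annotation, membership index per SNP).
    """
    if M < 1000:
        raise ValueError("M must be at least 1000")
    if not np.isclose(sum(a.snp_fraction for a in annotations), 1.0):
        raise ValueError("annotation SNP fractions must partition the genome")
    if rng is None:
        rng = np.random.default_rng(seed)

    bounds = np.linspace(0, M, n_blocks + 1).astype(int)
    block_means = rng.gamma(gamma[0], gamma[1], size=n_blocks)
    l2 = np.empty(M)
    for bnum in range(n_blocks):
        lo, hi = bounds[bnum], bounds[bnum + 1]
        l2[lo:hi] = 1.0 + block_means[bnum] * rng.gamma(2.0, 0.5, size=hi - lo)

    # exact annotation sizes, assigned by a random permutation
    sizes = np.floor(np.array([a.snp_fraction for a in annotations]) * M).astype(int)
    sizes[0] += M - sizes.sum()
    membership = np.repeat(np.arange(len(annotations)), sizes)
    rng.shuffle(membership)

    snp_ids = [f"rs{j}" for j in range(M)]
    table = pd.DataFrame({"L2": l2}, index=pd.Index(snp_ids, name="SNP"))
    for ci, a in enumerate(annotations):
        table[a.name] = np.where(membership == ci, l2, 0.0)

    size_map = {a.name: int(sizes[ci]) for ci, a in enumerate(annotations)}
    overlaps = {
        (a.name, b.name): (size_map[a.name] if a.name == b.name else 0)
        for a in annotations for b in annotations
    }
    genome = GENOME_ANNOTATION
    if genome not in size_map:
        size_map[genome] = M
        for a in annotations:
            overlaps[(a.name, genome)] = size_map[a.name]
        overlaps[(genome, genome)] = M
    ann_set = AnnotationSet(
        sizes=size_map, overlaps=dict(overlaps), total_m=M, genome_annotation=genome
    )
    return LDScores(table), ann_set, membership


def _psd_factor(m: np.ndarray, what: str) -> np.ndarray:
    w, q = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError(f"{what} is not positive semidefinite (min eigenvalue {w.min():.3g})")
    return q * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class SyntheticStudy:
    sumstats: list[CleanedSumstats]
    ld: LDScores
    annotations: AnnotationSet
    truth: TruthRecord

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ss in self.sumstats:
            ss.write(outdir / f"{ss.trait.name}.sumstats.gz")
        self.ld.write(outdir / "ldscores.tsv")
        pd.DataFrame([self.annotations.sizes]).to_csv(outdir / "annot_sizes.csv", index=False)
        names = self.annotations.names
        ov = pd.DataFrame(
            [[self.annotations.overlap(c, t) for t in names] for c in names],
            index=names, columns=names,
        )
        ov.to_csv(outdir / "annot_overlaps.csv")
        self.truth.to_json(outdir / "truth.json")


def simulate_sumstats(spec: GenerativeSpec) -> SyntheticStudy:
    """Draw a complete study (sumstats + LD scores + truth) from a spec.

    z-vectors are built as sums of independent Gaussian components, one for
    the intercept matrix and one per annotation, which reproduces the
    per-SNP covariance of the stratified-LDSC expectation exactly.
    """
    rng = np.random.default_rng(spec.seed)
    ld, ann_set, membership = make_ld_scores(
        spec.M, spec.annotations, rng=rng,
        n_blocks=spec.ld_n_blocks, gamma=spec.ld_gamma,
    )
    k = spec.k
    sqrt_n = np.sqrt(spec.N)
    B = spec.intercept_true()
    LB = _psd_factor(B, "intercept matrix (overlap/confound)")
    z = rng.standard_normal((spec.M, k)) @ LB.T

    taus = spec.tau_true()
    for ci, a in enumerate(spec.annotations):
        A_c = np.outer(sqrt_n, sqrt_n) * taus[a.name]
        LA = _psd_factor(A_c, f"annotation {a.name} covariance component")
        l_c = ld.table[a.name].to_numpy()
        w = np.sqrt(l_c / ann_set.sizes[a.name])
        z += w[:, None] * (rng.standard_normal((spec.M, k)) @ LA.T)

    maf = rng.uniform(0.05, 0.5, size=spec.M)
    sumstats = []
    for i in range(k):
        table = pd.DataFrame(
            {
                "A1": "A", "A2": "G", "Z": z[:, i], "N": spec.N[i], "MAF": maf,
            },
            index=ld.table.index,
        )
        meta = TraitMeta(name=spec.trait_names[i], measurement="continuous",
                         n_total=float(spec.N[i]))
        sumstats.append(CleanedSumstats(trait=meta, table=table))

    return SyntheticStudy(
        sumstats=sumstats, ld=ld, annotations=ann_set,
        truth=TruthRecord.from_spec(spec),
    )


@dataclass
class SyntheticParcellation:
    parcellation: "SphericalParcellation"
    class_map_a: np.ndarray
    class_map_b: np.ndarray
    continuous_map: np.ndarray


def simulate_parcellation(
    n_regions: int,
    n_classes: int,
    coupling: float = 0.0,
    seed: int | None = None,
    noise_sd: float = 1.0,
) -> SyntheticParcellation:
    """Random spherical parcellation with a coupled pair of categorical maps.

    Centroids are uniform on the left-facing hemisphere cap of the unit
    sphere (the bilateral-average convention: one centroid per region
    pair). Map B copies map A with probability ``coupling`` per region and
    is resampled uniformly otherwise; the continuous map is map A's class
    index plus unit-scale Gaussian noise.
    """
    from .topo_annotation import SphericalParcellation

    if n_regions < n_classes:
        raise ValueError("need at least as many regions as classes")
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    coords = rng.standard_normal((n_regions, 3))
    coords /= np.linalg.norm(coords, axis=1)[:, None]
    coords[:, 0] = -np.abs(coords[:, 0])  # left hemisphere cap

    parc = SphericalParcellation(
        names=[f"region{i + 1}" for i in range(n_regions)],
        coords=coords,
        hemisphere=np.array(["L"] * n_regions),
    )
    a = np.concatenate([
        np.arange(n_classes), rng.integers(0, n_classes, size=n_regions - n_classes)
    ])
    rng.shuffle(a)
    resample = rng.integers(0, n_classes, size=n_regions)
    b = np.where(rng.random(n_regions) < coupling, a, resample)
    cont = a.astype(float) + noise_sd * rng.standard_normal(n_regions)
    return SyntheticParcellation(parc, a, b, cont)
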