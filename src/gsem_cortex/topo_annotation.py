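"""Spin-permutation comparison of parcel maps on the sphere.

Spatial null models for parcellated cortical maps: each permutation applies
a uniformly random 3D rotation to the left-hemisphere region centroids (and
its x-mirrored counterpart to the right hemisphere, preserving hemispheric
symmetry), then relabels every region by its nearest original centroid
within the same hemisphere. Repeated labels are permitted — the relabeling
is a surjection, which is the standard behaviour of centroid-level spins.

Categorical map pairs are compared with a Fisher exact dependence test on
their r x c contingency table (Monte-Carlo evaluation of the Freeman-Halton
extension with fixed margins; the classic exact test for 2 x 2 tables);
continuous maps grouped by factor label are compared with a one-way omnibus
F statistic. In both cases the spin p-value uses the plus-one permutation
convention p = (1 + #{null at least as extreme}) / (n_spins + 1), so the
smallest attainable value is 1/(n_spins+1), the permutation floor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)


@dataclass
class SphericalParcellation:
    """Region centroids on the unit sphere, with hemisphere labels."""

    names: list[str]
    coords: np.ndarray           # n x 3, unit norm rows
    hemisphere: np.ndarray       # array of "L"/"R"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length centroid")
        self.coords = self.coords / norms[:, None]
        if len(set(self.names)) != len(self.names):
            raise ValueError("region labels must be unique")
        self.hemisphere = np.asarray(self.hemisphere)
        for hemi in np.unique(self.hemisphere):
            sub = self.coords[self.hemisphere == hemi]
            d = np.linalg.norm(sub[:, None] - sub[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            if d.min() < 1e-12:
                raise ValueError(f"duplicate centroids in hemisphere {hemi}")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def read(cls, path: str | Path) -> "SphericalParcellation":
        df = pd.read_csv(path)
        df.columns = [c.lower() for c in df.columns]
        return cls(
            names=df["region"].astype(str).tolist(),
            coords=df[["x", "y", "z"]].to_numpy(dtype=float),
            hemisphere=df["hemisphere"].astype(str).to_numpy(),
        )

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"region": self.names, "hemisphere": self.hemisphere,
             "x": self.coords[:, 0], "y": self.coords[:, 1], "z": self.coords[:, 2]}
        ).to_csv(path, index=False)


def load_dk_centroids() -> SphericalParcellation:
    """Synthetic stand-in centroids for the 34 bilateral Desikan-Killiany regions.

    The coordinates are deterministic random points on the left-hemisphere
    cap of the unit sphere — a synthetic placeholder carrying the standard
    region names, not FreeSurfer-derived geometry. Replace with real
    centroids via :meth:`SphericalParcellation.read` for production use.
    """
    path = Path(__file__).parent / "data" / "dk_centroids_synthetic.csv"
    return SphericalParcellation.read(path)


@dataclass
class SpinResult:
    observed_stat: float
    null_stats: np.ndarray = field(repr=False)
    p_spin: float
    n_spins: int
    seed: int | None = None
    flag: str | None = None
    q_value: float | None = None


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation in SO(3) via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))[None, :]
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def spin_permutations(
    parc: SphericalParcellation,
    n_spins: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate nearest-centroid spin relabelings, (n_spins, n_regions).

    Row s maps each region r to the original region whose centroid is
    nearest to r's rotated centroid within r's hemisphere; a spun map is
    ``values[perms[s]]``. Right-hemisphere centroids rotate by the
    x-mirrored counterpart of the left-hemisphere rotation so symmetric
    parcellations spin symmetrically. Equidistant candidates tie-break
    toward the lower region index (occurrences logged).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(parc)
    hemis = np.unique(parc.hemisphere)
    for hemi in hemis:
        if (parc.hemisphere == hemi).sum() < 3:
            raise ValueError(f"need at least 3 regions per hemisphere (got hemisphere {hemi})")
    mirror = np.diag([-1.0, 1.0, 1.0])
    perms = np.empty((n_spins, n), dtype=np.intp)
    n_ties = 0
    idx_by_hemi = {h: np.where(parc.hemisphere == h)[0] for h in hemis}
    for s in range(n_spins):
        rot = _random_rotation(rng)
        for hemi in hemis:
            idx = idx_by_hemi[hemi]
            r = rot if hemi == "L" else mirror @ rot @ mirror
            rotated = parc.coords[idx] @ r.T
            d = np.linalg.norm(rotated[:, None, :] - parc.coords[idx][None, :, :], axis=2)
            nearest = np.argmin(d, axis=1)
            mins = d[np.arange(len(idx)), nearest]
            n_ties += int(np.sum((d <= mins[:, None] + 1e-12).sum(axis=1) > 1))
            perms[s, idx] = idx[nearest]
    if n_ties:
        logger.info("spin relabeling: %d equidistant ties broken toward lower region index", n_ties)
    return perms


# ---------------------------------------------------------------------------
# Fisher exact dependence (Freeman-Halton, Monte-Carlo with fixed margins)
# ---------------------------------------------------------------------------

def _one_hot(labels: np.ndarray, n_levels: int) -> np.ndarray:
    """(rows, n) int labels -> (rows, n_levels, n) float32 indicators."""
    rows, n = labels.shape
    out = np.zeros((rows, n_levels, n), dtype=np.float32)
    r = np.repeat(np.arange(rows), n)
    out[r, labels.ravel(), np.tile(np.arange(n), rows)] = 1.0
    return out


def _fisher_exceed_counts(
    a_rows: np.ndarray, b: np.ndarray, n_mc: int, rng: np.random.Generator,
    chunk: int = 500,
) -> np.ndarray:
    """Monte-Carlo Freeman-Halton exceedance counts per labeling row vs ``b``.

    All rows share one set of fixed-margin null draws (random permutations
    of ``b``), which fixes both margins of every simulated table. Within a
    row the table-probability constant depends only on the margins, so the
    extremeness comparison reduces to the sum of log-factorial cell counts;
    the returned integer count is #{draws at least as extreme}, so the MC
    Fisher p is (1 + count)/(n_mc + 1). Tables are accumulated through a
    single one-hot matrix product per draw chunk.
    """
    a_rows = np.atleast_2d(a_rows)
    S, n = a_rows.shape
    ra = int(a_rows.max()) + 1
    cb = int(b.max()) + 1
    lut = gammaln(np.arange(n + 1) + 1.0).astype(np.float32)

    a_hot = _one_hot(a_rows, ra).reshape(S * ra, n)
    perm_idx = np.argsort(rng.random((n_mc, n)), axis=1)
    b_perm = b[perm_idx]  # n_mc x n

    def stat(b_mat: np.ndarray) -> np.ndarray:
        # (Y, n) -> (S, Y) sum over cells of log-factorial counts
        b_hot = _one_hot(b_mat, cb).reshape(b_mat.shape[0] * cb, n)
        counts = (a_hot @ b_hot.T).reshape(S, ra, b_mat.shape[0], cb)
        return lut[counts.astype(np.intp)].sum(axis=(1, 3))

    obs = stat(b[None, :])[:, 0]  # (S,)
    exceed = np.zeros(S, dtype=np.int64)
    for lo in range(0, n_mc, chunk):
        exceed += (stat(b_perm[lo:lo + chunk]) >= obs[:, None] - 1e-4).sum(axis=1)
    return exceed


def _cramers_v(a_rows: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cramér's V of each labeling row of ``a_rows`` against ``b``."""
    a_rows = np.atleast_2d(a_rows)
    S, n = a_rows.shape
    ra = int(a_rows.max()) + 1
    cb = int(b.max()) + 1
    a_hot = _one_hot(a_rows, ra)                       # (S, ra, n)
    b_hot = _one_hot(b[None, :], cb)[0]                # (cb, n)
    tables = a_hot @ b_hot.T                           # (S, ra, cb)
    rows = tables.sum(axis=2, keepdims=True)
    cols = tables.sum(axis=1, keepdims=True)
    expected = rows * cols / n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(expected > 0, (tables - expected) ** 2 / expected, 0.0).sum(axis=(1, 2))
    r_eff = (rows[:, :, 0] > 0).sum(axis=1)
    c_eff = (cols[:, 0, :] > 0).sum(axis=1)
    denom = n * np.maximum(np.minimum(r_eff, c_eff) - 1, 1)
    return np.sqrt(chi2 / denom)


def _encode(labels: Sequence) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes.astype(np.intp)


def fisher_exact_p(
    a: Sequence, b: Sequence, n_mc: int = 100_000, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Fisher exact dependence p for two categorical maps.

    Exact (scipy network algorithm) for 2 x 2 tables; seeded Monte-Carlo
    sampling of fixed-margin tables otherwise.
    """
    ac, bc = _encode(a), _encode(b)
    if ac.max() == 1 and bc.max() == 1:
        table = np.zeros((2, 2), dtype=int)
        np.add.at(table, (ac, bc), 1)
        return float(stats.fisher_exact(table)[1])
    if rng is None:
        rng = np.random.default_rng(seed)
    exceed = _fisher_exceed_counts(ac[None, :], bc, n_mc, rng)[0]
    return float((1.0 + exceed) / (n_mc + 1.0))


def categorical_spin_test(
    a: Sequence,
    b: Sequence,
    spins: np.ndarray,
    n_mc: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SpinResult:
    """Spin test for dependence between two categorical parcel maps.

    The observed statistic is the Fisher exact p of map ``a`` vs ``b``; the
    null spins map ``a`` and recomputes the same statistic with the same
    Monte-Carlo draw budget, and p_spin is the plus-one-corrected fraction
    of spins whose Fisher p is at most the observed one. Because the
    Monte-Carlo p is discrete (multiples of 1/(n_mc+1)), exact ties in p
    are resolved by the table's Cramér's V: a tied spin counts as "at
    least as extreme" only when its dependence is at least as strong.
    This keeps the test exchangeable under the null while letting a
    maximally dependent observed map reach the permutation floor.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ac, bc = _encode(a), _encode(b)
    n_spins = spins.shape[0]
    if ac.max() == 0 or bc.max() == 0:
        warnings.warn("a map with a single class carries no dependence information", stacklevel=2)
        return SpinResult(np.nan, np.full(n_spins, np.nan), 1.0, n_spins, seed,
                          flag="single_class")
    stacked = np.vstack([ac[None, :], ac[spins]])
    exceed = _fisher_exceed_counts(stacked, bc, n_mc, rng)
    v = _cramers_v(stacked, bc)
    ps = (1.0 + exceed) / (n_mc + 1.0)
    p_obs, p_null = ps[0], ps[1:]
    more_extreme = (exceed[1:] < exceed[0]) | (
        (exceed[1:] == exceed[0]) & (v[1:] >= v[0] - 1e-12)
    )
    p_spin = (1.0 + np.sum(more_extreme)) / (n_spins + 1.0)
    return SpinResult(float(p_obs), p_null, float(p_spin), n_spins, seed)


def _omnibus_f(values: np.ndarray, groups: np.ndarray, n_groups: int) -> float:
    n = values.size
    counts = np.bincount(groups, minlength=n_groups)
    sums = np.bincount(groups, weights=values, minlength=n_groups)
    present = counts > 0
    g = int(present.sum())
    if g < 2:
        return np.nan
    means = np.where(present, sums / np.maximum(counts, 1), 0.0)
    grand = values.mean()
    ssb = float(np.sum(counts[present] * (means[present] - grand) ** 2))
    ssw = float(np.sum((values - means[groups]) ** 2))
    if ssw <= 0:
        return np.inf
    return (ssb / (g - 1)) / (ssw / (n - g))


def continuous_spin_test(
    factor_labels: Sequence,
    maps: Mapping[str, Sequence[float]],
    spins: np.ndarray,
) -> dict[str, SpinResult]:
    """Omnibus-F spin tests of continuous maps across factor groups, with
    Benjamini-Hochberg q-values across the map collection."""
    groups = _encode(factor_labels)
    n_groups = int(groups.max()) + 1
    n_spins = spins.shape[0]
    spun_groups = groups[spins]  # (n_spins, n)
    out: dict[str, SpinResult] = {}
    ps, keys = [], []
    for name, vals in maps.items():
        v = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"map {name} has non-finite values")
        if n_groups < 2 or np.allclose(v, v[0]):
            flag = "single_group" if n_groups < 2 else "constant_map"
            out[name] = SpinResult(np.nan, np.full(n_spins, np.nan), 1.0, n_spins, flag=flag)
            ps.append(1.0)
            keys.append(name)
            continue
        f_obs = _omnibus_f(v, groups, n_groups)
        f_null = np.array([_omnibus_f(v, spun_groups[s], n_groups) for s in range(n_spins)])
        p = (1.0 + np.sum(f_null >= f_obs - 1e-12)) / (n_spins + 1.0)
        out[name] = SpinResult(float(f_obs), f_null, float(p), n_spins)
        ps.append(p)
        keys.append(name)
    if keys:
        qs = stats.false_discovery_control(np.asarray(ps), method="bh")
        for name, q in zip(keys, qs):
            out[name].q_value = float(q)
    return out


def spin_results_table(results: Mapping[str, SpinResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"map": name, "observed_stat": r.observed_stat, "p_spin": r.p_spin,
             "q": r.q_value, "n_spins": r.n_spins, "flag": r.flag}
            for name, r in results.items()
        ]
    )
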