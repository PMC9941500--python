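"""Reading, QC-filtering and harmonization of GWAS summary statistics.

The munging step mirrors the standard LDSC preprocessing conventions:
restrict to a reference SNP list (HapMap3 in typical applications), drop
low-frequency and poorly imputed variants, drop strand-ambiguous (A/T, C/G)
pairs, and align the sign of every z-statistic to the reference effect
allele. Binary traits carry cohort case/control counts from which the
effective sample size 4/(1/cases + 1/controls), summed over cohorts, is
computed; with effective N the downstream liability conversion uses a sample
prevalence of 0.5.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

# Recognized header aliases (upper-cased) for each mandatory/optional column.
COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "SNP": ("SNP", "RSID", "RS_ID", "MARKERNAME", "ID", "RSNUMBER"),
    "A1": ("A1", "EFFECT_ALLELE", "ALLELE1", "EA"),
    "A2": ("A2", "OTHER_ALLELE", "ALLELE2", "NON_EFFECT_ALLELE", "NEA", "A0"),
    "Z": ("Z", "ZSCORE", "Z_STAT"),
    "BETA": ("BETA", "B", "EFFECT", "EST"),
    "OR": ("OR", "ODDS_RATIO"),
    "SE": ("SE", "STDERR", "STD_ERR"),
    "N": ("N", "NEFF", "N_EFF", "TOTALN", "WEIGHT"),
    "MAF": ("MAF", "FREQ", "FRQ", "EAF", "AF", "FREQ1"),
    "INFO": ("INFO", "IMPINFO", "RSQ"),
}


class SumstatsConfigError(ValueError):
    """Raised when a raw summary-statistics table misses a mandatory column."""


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One SNP's association summary for a single trait."""

    snp_id: str
    a1: str
    a2: str
    z: float
    n: float
    maf: float
    info: float | None = None

    def __post_init__(self):
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: identical alleles {self.a1}")
        if not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside (0, 0.5]")
        if not math.isfinite(self.z):
            raise ValueError(f"{self.snp_id}: non-finite z")


@dataclass
class TraitMeta:
    """Trait-level metadata needed for effective N and liability conversion."""

    name: str
    measurement: str = "continuous"  # "continuous" | "binary"
    n_total: float | None = None
    cohorts: Sequence[tuple[float, float]] | None = None  # (cases, controls)
    sample_prev: float | None = None
    pop_prev: float | None = None

    def __post_init__(self):
        if self.measurement not in ("continuous", "binary"):
            raise ValueError(f"unknown measurement type {self.measurement!r}")
        if self.pop_prev is not None and not (0 < self.pop_prev < 1):
            raise ValueError("population prevalence must lie in (0, 1)")
        if self.measurement == "binary" and self.cohorts is None and self.n_total is None:
            raise ValueError(
                "binary traits need cohort case/control counts or a precomputed effective N"
            )

    @property
    def effective_n_total(self) -> float | None:
        if self.cohorts is not None:
            return effective_n(self.cohorts)
        return self.n_total


@dataclass
class CleanedSumstats:
    """QC-passed, reference-aligned summary statistics for one trait.

    ``table`` is indexed by SNP id with columns A1, A2, Z, N, MAF and
    (optionally) INFO; A1 is the reference effect allele after munging.
    """

    trait: TraitMeta
    table: pd.DataFrame
    filter_log: dict[str, int] = field(default_factory=dict)

    @property
    def records(self) -> dict[str, VariantRecord]:
        has_info = "INFO" in self.table.columns
        out = {}
        for snp, row in self.table.iterrows():
            out[snp] = VariantRecord(
                snp_id=snp, a1=row["A1"], a2=row["A2"], z=float(row["Z"]),
                n=float(row["N"]), maf=float(row["MAF"]),
                info=float(row["INFO"]) if has_info else None,
            )
        return out

    @property
    def snp_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path: str | Path) -> None:
        """Write the munged table (SNP, A1, A2, Z, N) as gzipped TSV."""
        out = self.table.reset_index()[["SNP", "A1", "A2", "Z", "N"]]
        with gzip.open(path, "wt") as fh:
            out.to_csv(fh, sep="\t", index=False)


def effective_n(cohorts: Iterable[tuple[float, float]]) -> float:
    """Sum of per-cohort effective sample sizes 4*v*(1-v)*N.

    With v = cases/(cases+controls) this equals 4/(1/cases + 1/controls) per
    cohort; a balanced cohort contributes its full N.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("empty cohort list")
    total = 0.0
    for cases, controls in cohorts:
        if cases <= 0 or controls <= 0:
            raise ValueError("case and control counts must be positive")
        n = cases + controls
        v = cases / n
        total += 4.0 * v * (1.0 - v) * n
    return total


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read a reference SNP list: whitespace-delimited SNP, A1, A2 columns."""
    ref = pd.read_csv(path, sep=r"\s+")
    ref.columns = [c.upper() for c in ref.columns]
    missing = {"SNP", "A1", "A2"} - set(ref.columns)
    if missing:
        raise SumstatsConfigError(f"reference list missing columns {sorted(missing)}")
    return ref.set_index("SNP")[["A1", "A2"]]


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    upper = {c.upper(): c for c in columns}
    found: dict[str, str] = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in upper:
                found[canonical] = upper[alias]
                break
    return found


def _read_raw(raw: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(raw, pd.DataFrame):
        return raw.copy()
    return pd.read_csv(raw, sep=r"\s+")


def munge(
    raw_table: str | Path | pd.DataFrame,
    reference: str | Path | pd.DataFrame,
    trait: TraitMeta | None = None,
    maf_min: float = 0.01,
    info_min: float = 0.9,
) -> CleanedSumstats:
    """QC-filter and harmonize one trait's summary statistics.

    Filters (applied sequentially; each row is charged to the first filter it
    fails, so retained + per-filter counts always add to the input row count):

    1. duplicate SNP ids (all copies dropped, with a warning),
    2. SNP absent from the reference list,
    3. invalid or strand-ambiguous (A/T, C/G) alleles,
    4. alleles that cannot be matched to the reference pair either directly
       or swapped (swapped matches flip the z sign),
    5. non-finite z,
    6. MAF below ``maf_min``,
    7. INFO below ``info_min`` (silently skipped, with a logged warning, when
       the table carries no INFO column).

    Beta/SE input is converted to z = beta/se and OR/SE to log(OR)/se before
    filtering. When a per-SNP N column is present it takes precedence over
    any trait-level total N.
    """
    df = _read_raw(raw_table)
    if isinstance(reference, pd.DataFrame):
        ref = reference.copy()
        if "SNP" in ref.columns:
            ref = ref.set_index("SNP")
        ref = ref[["A1", "A2"]]
    else:
        ref = read_reference(reference)
    if len(ref) == 0:
        raise SumstatsConfigError("reference SNP list is empty")

    cols = _resolve_columns(df.columns)
    for mandatory in ("SNP", "A1", "A2"):
        if mandatory not in cols:
            raise SumstatsConfigError(f"missing mandatory column: {mandatory}")

    work = pd.DataFrame(index=df.index)
    work["SNP"] = df[cols["SNP"]].astype(str)
    work["A1"] = df[cols["A1"]].astype(str).str.upper()
    work["A2"] = df[cols["A2"]].astype(str).str.upper()

    # Effect column: Z directly, or beta/SE, or OR/SE.
    if "Z" in cols:
        work["Z"] = pd.to_numeric(df[cols["Z"]], errors="coerce")
    elif "BETA" in cols and "SE" in cols:
        work["Z"] = pd.to_numeric(df[cols["BETA"]], errors="coerce") / pd.to_numeric(
            df[cols["SE"]], errors="coerce"
        )
    elif "OR" in cols and "SE" in cols:
        work["Z"] = np.log(pd.to_numeric(df[cols["OR"]], errors="coerce")) / pd.to_numeric(
            df[cols["SE"]], errors="coerce"
        )
    else:
        raise SumstatsConfigError("missing mandatory column: Z (or BETA/OR with SE)")

    if "N" in cols:
        work["N"] = pd.to_numeric(df[cols["N"]], errors="coerce")
    elif trait is not None and trait.effective_n_total is not None:
        work["N"] = float(trait.effective_n_total)
    else:
        raise SumstatsConfigError("missing mandatory column: N (and no trait-level N)")

    if "MAF" in cols:
        freq = pd.to_numeric(df[cols["MAF"]], errors="coerce")
        work["MAF"] = np.minimum(freq, 1.0 - freq)  # fold allele frequency to minor
    else:
        work["MAF"] = np.nan
    has_info = "INFO" in cols
    if has_info:
        work["INFO"] = pd.to_numeric(df[cols["INFO"]], errors="coerce")
    else:
        logger.warning("no INFO column found; INFO filter skipped")

    log: dict[str, int] = {"input": len(work)}
    keep = work

    dup = keep["SNP"].duplicated(keep=False)
    if dup.any():
        logger.warning("dropping %d rows with duplicated SNP ids", int(dup.sum()))
    log["duplicate_id"] = int(dup.sum())
    keep = keep[~dup]

    in_ref = keep["SNP"].isin(ref.index)
    log["not_in_reference"] = int((~in_ref).sum())
    keep = keep[in_ref]

    valid = keep["A1"].isin(VALID_ALLELES) & keep["A2"].isin(VALID_ALLELES)
    ambiguous = valid & np.array(
        [(a1, a2) in _AMBIGUOUS for a1, a2 in zip(keep["A1"], keep["A2"])], dtype=bool
    )
    bad_alleles = (~valid) | ambiguous
    log["ambiguous_or_invalid_alleles"] = int(bad_alleles.sum())
    keep = keep[~bad_alleles]

    ref_a1 = ref["A1"].reindex(keep["SNP"]).to_numpy()
    ref_a2 = ref["A2"].reindex(keep["SNP"]).to_numpy()
    direct = (keep["A1"].to_numpy() == ref_a1) & (keep["A2"].to_numpy() == ref_a2)
    swapped = (keep["A1"].to_numpy() == ref_a2) & (keep["A2"].to_numpy() == ref_a1)
    log["allele_mismatch"] = int((~(direct | swapped)).sum())
    keep = keep[direct | swapped]
    flip = swapped[direct | swapped]
    keep.loc[flip, "Z"] = -keep.loc[flip, "Z"]
    keep.loc[flip, ["A1", "A2"]] = keep.loc[flip, ["A2", "A1"]].to_numpy()

    finite = np.isfinite(keep["Z"]) & np.isfinite(keep["N"]) & (keep["N"] > 0)
    log["nonfinite"] = int((~finite).sum())
    keep = keep[finite]

    if keep["MAF"].notna().any():
        maf_ok = keep["MAF"] >= maf_min
        log["maf"] = int((~maf_ok).sum())
        keep = keep[maf_ok]
    else:
        log["maf"] = 0

    if has_info:
        info_ok = keep["INFO"].fillna(1.0) >= info_min
        log["info"] = int((~info_ok).sum())
        keep = keep[info_ok]
    else:
        log["info"] = 0

    log["retained"] = len(keep)
    if len(keep) == 0:
        raise ValueError("zero SNPs survived munging")
    for name, count in log.items():
        if name not in ("input", "retained") and count:
            logger.info("munge: removed %d SNPs (%s)", count, name)

    keep = keep.set_index("SNP")
    if trait is None:
        trait = TraitMeta(name="trait")
    return CleanedSumstats(trait=trait, table=keep, filter_log=log)
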