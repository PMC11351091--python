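"""GWAS summary-statistics containers, file I/O, and allele harmonization.

Summary statistics are kept in :class:`pandas.DataFrame` objects wrapped by
light dataclasses that enforce the domain invariants (unique SNP ids, positive
standard errors, ACGT alleles).  Harmonization aligns an exposure table and an
outcome table onto a common effect-allele orientation, removing palindromic
(A/T, C/G) variants unconditionally and attempting strand-complement
reconciliation before declaring an allele pair incompatible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of a summary-statistics table
SUMSTATS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos_bp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: tiny positive floor so p-values stay inside (0, 1]
P_FLOOR = 1e-300


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele estimate: log-odds for binary traits,
    SD units for quantitative traits.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be single A/C/G/T bases")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}: pval outside (0, 1]")
        if not self.n > 0:
            raise ValueError(f"{self.snp_id}: n must be > 0")


@dataclass
class SumstatsTable:
    """One trait's GWAS summary statistics (one row per SNP).

    Parameters
    ----------
    trait_id : str
        Identifier of the trait (e.g. a metabolite or "sepsis").
    trait_type : {"binary", "quantitative"}
        Scale of ``beta``: log-odds vs SD units.
    df : pandas.DataFrame
        Table with :data:`SUMSTATS_COLUMNS`; ``snp_id`` must be unique.
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"sumstats table missing columns {missing}")
        if len(self.df) == 0:
            raise ValueError(f"{self.trait_id}: empty summary-statistics table")
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"{self.trait_id}: duplicate snp_id {dups[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[GwasRecord]:
        for row in self.df.itertuples(index=False):
            yield GwasRecord(
                snp_id=row.snp_id,
                chrom=str(row.chrom),
                pos_bp=int(row.pos_bp),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=float(row.n),
            )

    def subset(self, snp_ids) -> "SumstatsTable":
        """Rows whose ``snp_id`` is in ``snp_ids`` (original order preserved)."""
        keep = self.df["snp_id"].isin(set(snp_ids))
        return SumstatsTable(self.trait_id, self.trait_type, self.df.loc[keep])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


#: columns of a harmonized exposure/outcome pair table
HARMONIZED_COLUMNS = [
    "snp_id",
    "beta_x",
    "se_x",
    "eaf_x",
    "n_x",
    "beta_y",
    "se_y",
    "eaf_y",
    "n_y",
]


@dataclass
class HarmonizedSet:
    """Per-SNP exposure/outcome effect pairs on a common effect-allele orientation."""

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    exposure_type: str = "quantitative"
    outcome_type: str = "binary"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"harmonized table missing columns {missing}")
        if len(self.df) and not ((self.df["se_x"] > 0).all() and (self.df["se_y"] > 0).all()):
            raise ValueError("harmonized pairs must have positive standard errors")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = self.df["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.df.loc[keep],
            self.n_dropped_palindromic,
            self.n_dropped_incompatible,
            self.exposure_type,
            self.outcome_type,
            dict(self.meta),
        )

    def drop(self, snp_ids) -> "HarmonizedSet":
        keep = ~self.df["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.df.loc[keep],
            self.n_dropped_palindromic,
            self.n_dropped_incompatible,
            self.exposure_type,
            self.outcome_type,
            dict(self.meta),
        )

    def to_tsv(self, path) -> None:
        self.df[HARMONIZED_COLUMNS].to_csv(path, sep="\t", index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G).

    Palindromic variants read the same on both strands, so the effect-allele
    orientation cannot be recovered from the alleles alone; they are excluded
    from harmonization unconditionally.
    """
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValueError(f"non-ACGT allele in ({a1!r}, {a2!r})")
    if a1 == a2:
        raise ValueError("alleles must differ")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_id: str | None = None,
) -> SumstatsTable:
    """Load a tab-separated summary-statistics file.

    Parameters
    ----------
    path : path-like
        UTF-8 TSV with a header row. ``.`` or empty fields are missing.
    column_map : mapping, optional
        Maps canonical names (``snp_id``, ``chrom``, ``pos_bp``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pval``, ``n``) to the column names in the file.  Canonical names
        already present in the file need not be mapped.
    trait_type : {"quantitative", "binary"}
    trait_id : str, optional
        Defaults to the file stem.

    Rows with missing beta/se, non-positive se, non-ACGT alleles (e.g.
    indels), out-of-range eaf, or invalid p are dropped and counted in the
    log.  A p-value grossly inconsistent with |beta/se| under a two-sided
    normal (beyond 10% relative tolerance) is logged but the row is kept
    with the p-value as given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", na_values=[".", ""], dtype={0: str})
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    cols = [c for c in SUMSTATS_COLUMNS if c in raw.columns]
    if "snp_id" not in cols or "beta" not in cols or "se" not in cols:
        raise ValueError(
            f"{path}: no mappable columns (need at least snp_id, beta, se; got {list(raw.columns)})"
        )
    df = raw.copy()
    for col, default in (("chrom", "0"), ("pos_bp", 0), ("eaf", np.nan), ("pval", np.nan), ("n", np.nan)):
        if col not in df.columns:
            df[col] = default
    for col in ("effect_allele", "other_allele"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing allele column {col!r}")
        df[col] = df[col].astype(str).str.upper()

    n_in = len(df)
    numeric = ["pos_bp", "eaf", "beta", "se", "pval", "n"]
    df[numeric] = df[numeric].apply(pd.to_numeric, errors="coerce")
    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)

    ok = (
        df["beta"].notna()
        & df["se"].notna()
        & (df["se"] > 0)
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    ok &= df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    ok &= df["pval"].isna() | ((df["pval"] > 0) & (df["pval"] <= 1))
    ok &= df["n"].isna() | (df["n"] > 0)
    n_dropped = int(n_in - ok.sum())
    if n_dropped:
        logger.warning("%s: dropped %d/%d malformed rows", path.name, n_dropped, n_in)
    df = df.loc[ok].copy()
    if len(df) == 0:
        raise ValueError(f"{path}: zero rows survive validation")

    # fill p from the normal approximation where absent; flag inconsistencies
    z = (df["beta"] / df["se"]).abs()
    p_implied = np.clip(2.0 * stats.norm.sf(z), P_FLOOR, 1.0)
    missing_p = df["pval"].isna()
    df.loc[missing_p, "pval"] = p_implied[missing_p]
    with np.errstate(divide="ignore", invalid="ignore"):
        both = ~missing_p & (df["pval"] < 0.5) & (p_implied < 0.5)
        rel = np.abs(np.log(df["pval"].where(both)) - np.log(p_implied)) / np.abs(
            np.log(p_implied)
        )
    n_inconsistent = int((rel.where(both, 0) > 0.10).sum())
    if n_inconsistent:
        logger.warning(
            "%s: %d rows with p-value inconsistent with |beta/se| beyond 10%%",
            path.name,
            n_inconsistent,
        )
    df["eaf"] = df["eaf"].fillna(0.5)
    df["n"] = df["n"].fillna(df["n"].median() if df["n"].notna().any() else 0)
    if (df["n"] <= 0).any():
        raise ValueError(f"{path}: sample size column missing or non-positive")
    df = df.drop_duplicates(subset="snp_id", keep="first")
    return SumstatsTable(trait_id or path.stem, trait_type, df[SUMSTATS_COLUMNS])


def _orientation(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> int | None:
    """How the outcome allele pair maps onto the exposure pair.

    Returns +1 (aligned), -1 (flip outcome effect), or None (incompatible).
    Strand-complement reconciliation is attempted before giving up.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return 1
    if (ea_y, oa_y) == (oa_x, ea_x):
        return -1
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return 1
    if (cea, coa) == (oa_x, ea_x):
        return -1
    return None


def harmonize(exposure: SumstatsTable, outcome: SumstatsTable) -> HarmonizedSet:
    """Align exposure and outcome effects onto one effect-allele orientation.

    Keeps only SNPs present in both tables.  Palindromic SNPs are removed
    unconditionally (no allele-frequency inference).  When the outcome's
    effect allele matches the exposure's other allele (directly or after
    strand complement) the outcome beta is sign-flipped and its eaf becomes
    ``1 - eaf``.  Allele pairs that cannot be reconciled are dropped and
    counted.

    Raises
    ------
    ValueError
        If the tables share no SNPs.
    """
    ex = exposure.df.set_index("snp_id")
    ou = outcome.df.set_index("snp_id")
    shared = ex.index.intersection(ou.index)
    if len(shared) == 0:
        raise ValueError(
            f"no overlapping SNPs between {exposure.trait_id} and {outcome.trait_id}"
        )
    # deterministic order: exposure (chrom, pos, snp_id)
    exs = ex.loc[shared]
    order = np.lexsort(
        (shared.to_numpy(), exs["pos_bp"].to_numpy(), exs["chrom"].to_numpy())
    )
    shared = shared[order]

    rows = []
    n_pal = 0
    n_bad = 0
    for snp in shared:
        rx = ex.loc[snp]
        ry = ou.loc[snp]
        if is_palindromic(rx["effect_allele"], rx["other_allele"]) or is_palindromic(
            ry["effect_allele"], ry["other_allele"]
        ):
            n_pal += 1
            continue
        sign = _orientation(
            rx["effect_allele"], rx["other_allele"], ry["effect_allele"], ry["other_allele"]
        )
        if sign is None:
            n_bad += 1
            continue
        beta_y = sign * float(ry["beta"])
        eaf_y = float(ry["eaf"]) if sign == 1 else 1.0 - float(ry["eaf"])
        rows.append(
            {
                "snp_id": snp,
                "chrom": str(rx["chrom"]),
                "pos_bp": int(rx["pos_bp"]),
                "beta_x": float(rx["beta"]),
                "se_x": float(rx["se"]),
                "eaf_x": float(rx["eaf"]),
                "n_x": float(rx["n"]),
                "beta_y": beta_y,
                "se_y": float(ry["se"]),
                "eaf_y": eaf_y,
                "n_y": float(ry["n"]),
            }
        )
    if n_pal or n_bad:
        logger.info(
            "harmonize %s vs %s: %d pairs, %d palindromic dropped, %d incompatible dropped",
            exposure.trait_id,
            outcome.trait_id,
            len(rows),
            n_pal,
            n_bad,
        )
    cols = ["snp_id", "chrom", "pos_bp"] + HARMONIZED_COLUMNS[1:]
    df = pd.DataFrame(rows, columns=cols)
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        df=df,
        n_dropped_palindromic=n_pal,
        n_dropped_incompatible=n_bad,
        exposure_type=exposure.trait_type,
        outcome_type=outcome.trait_type,
    )
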