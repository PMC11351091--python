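"""Instrument selection for two-sample MR.

Covers the p-value screen, greedy LD clumping against a precomputed pairwise
r^2 table, instrument-strength statistics (R^2 and F), the weak-instrument
filter, and per-SNP Steiger directionality filtering on harmonized pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedSet, SumstatsTable

logger = logging.getLogger(__name__)


class LdTable:
    """Symmetric pairwise linkage-disequilibrium (r^2) lookup.

    Absent pairs are treated as r^2 = 0; a SNP with itself as r^2 = 1.
    """

    def __init__(self, entries=()):
        self._r2: dict[frozenset, float] = {}
        for snp_a, snp_b, r2 in entries:
            self.add(snp_a, snp_b, r2)

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 outside [0, 1]: {r2}")
        if snp_a != snp_b:
            self._r2[frozenset((snp_a, snp_b))] = float(r2)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(frozenset((snp_a, snp_b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path) -> "LdTable":
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        return cls(zip(df["snp_a"], df["snp_b"], df["r2"]))

    def to_tsv(self, path) -> None:
        rows = sorted((tuple(sorted(k)), v) for k, v in self._r2.items())
        df = pd.DataFrame(
            [(a, b, v) for (a, b), v in rows], columns=["snp_a", "snp_b", "r2"]
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class InstrumentStats:
    """Instrument strength of one SNP: variance explained and F-statistic."""

    snp_id: str
    r2: float
    f_stat: float


def select_by_pvalue(table: SumstatsTable, p_threshold: float) -> SumstatsTable | None:
    """Keep records with ``pval < p_threshold`` (strict), preserving order.

    Returns None when nothing survives (an empty table is not representable).
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    keep = table.df["pval"] < p_threshold
    if not keep.any():
        logger.warning("%s: no SNP passes p < %g", table.trait_id, p_threshold)
        return None
    return SumstatsTable(table.trait_id, table.trait_type, table.df.loc[keep])


def ld_clump(
    table: SumstatsTable,
    ld: LdTable,
    window_kb: int = 10_000,
    r2_threshold: float = 0.001,
) -> SumstatsTable:
    """Greedy LD clumping.

    Repeatedly takes the lowest-p unclaimed SNP as an index SNP and discards
    every unclaimed SNP on the same chromosome within ``window_kb`` of it
    whose r^2 with it is >= ``r2_threshold``.  Ties at equal p are broken by
    lower (chrom, pos).  Index SNPs are returned sorted by position.
    """
    df = table.df
    snp = df["snp_id"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos_bp"].to_numpy(dtype=np.int64)
    pval = df["pval"].to_numpy(dtype=float)
    order = np.lexsort((snp, pos, chrom, pval))
    window_bp = window_kb * 1000
    unclaimed = list(order)
    kept: list[int] = []
    while unclaimed:
        idx = unclaimed.pop(0)
        kept.append(idx)
        survivors = []
        for j in unclaimed:
            if (
                chrom[j] == chrom[idx]
                and abs(int(pos[j]) - int(pos[idx])) <= window_bp
                and ld.r2(snp[idx], snp[j]) >= r2_threshold
            ):
                continue
            survivors.append(j)
        unclaimed = survivors
    out = df.iloc[kept].sort_values(["chrom", "pos_bp", "snp_id"], kind="stable")
    return SumstatsTable(table.trait_id, table.trait_type, out)


def instrument_strength(record) -> InstrumentStats:
    """R^2 and F-statistic of one SNP from summary data.

    Uses the t-statistic approximation r^2 = t^2 / (t^2 + n - 2) with
    t = beta/se; F = r^2 (n - 2) / (1 - r^2), which reduces algebraically
    to t^2.
    """
    n = float(record.n)
    if n <= 2:
        raise ValueError(f"{record.snp_id}: need n > 2 for instrument strength")
    t2 = (float(record.beta) / float(record.se)) ** 2
    r2 = t2 / (t2 + n - 2.0)
    f_stat = r2 * (n - 2.0) / (1.0 - r2)
    return InstrumentStats(snp_id=record.snp_id, r2=r2, f_stat=f_stat)


def strength_table(table: SumstatsTable) -> pd.DataFrame:
    """Per-SNP instrument strength for a whole table."""
    t2 = (table.df["beta"] / table.df["se"]) ** 2
    n = table.df["n"].astype(float)
    r2 = t2 / (t2 + n - 2.0)
    f = r2 * (n - 2.0) / (1.0 - r2)
    return pd.DataFrame({"snp_id": table.df["snp_id"], "r2": r2, "f_stat": f})


def filter_weak(table: SumstatsTable, f_min: float = 10.0) -> SumstatsTable | None:
    """Drop SNPs with F-statistic below ``f_min`` (default 10).

    Returns None when every instrument is weak.
    """
    if f_min < 0:
        raise ValueError("f_min must be >= 0")
    f = strength_table(table)["f_stat"].to_numpy()
    keep = f >= f_min
    if not keep.any():
        logger.warning("%s: all instruments weak (F < %g)", table.trait_id, f_min)
        return None
    return SumstatsTable(table.trait_id, table.trait_type, table.df.loc[keep])


def steiger_filter(h: HarmonizedSet) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Per-SNP causal-direction (Steiger) filter on harmonized pairs.

    For each SNP, variance explained on each side is computed via
    r^2 = t^2/(t^2 + n - 2); the direction is "TRUE" iff the SNP explains
    strictly more variance in the exposure than in the outcome.  The
    two-sided Steiger p compares Fisher-z-transformed |r| values with
    variance 1/(n_x - 3) + 1/(n_y - 3).

    Returns the set restricted to direction-TRUE SNPs plus a per-SNP report
    ``(snp_id, r2_x, r2_y, direction, steiger_p)``.
    """
    df = h.df
    n_x = df["n_x"].to_numpy(float)
    n_y = df["n_y"].to_numpy(float)
    if (n_x <= 3).any() or (n_y <= 3).any():
        raise ValueError("Steiger filtering needs n > 3 on both sides")
    t2_x = (df["beta_x"] / df["se_x"]) ** 2
    t2_y = (df["beta_y"] / df["se_y"]) ** 2
    r2_x = (t2_x / (t2_x + n_x - 2.0)).to_numpy()
    r2_y = (t2_y / (t2_y + n_y - 2.0)).to_numpy()
    z = np.arctanh(np.sqrt(r2_x)) - np.arctanh(np.sqrt(r2_y))
    se = np.sqrt(1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0))
    pval = 2.0 * stats.norm.sf(np.abs(z) / se)
    direction = r2_x > r2_y  # strict: ties count as FALSE
    report = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "r2_x": r2_x,
            "r2_y": r2_y,
            "direction": np.where(direction, "TRUE", "FALSE"),
            "steiger_p": pval,
        }
    )
    kept = h.subset(df.loc[direction, "snp_id"])
    return kept, report
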