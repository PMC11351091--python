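"""Synthetic GWAS summary-statistics generator for exposure/mediator/outcome triplets.

Summary statistics are simulated directly (no individual-level genotypes):
for a SNP with minor-allele frequency ``maf`` and study size ``n`` the
sampling error of a standardized per-allele estimate is
``se = 1 / sqrt(2 maf (1 - maf) n)``, which makes the SE formula an exact
oracle for moment tests.

The generative model follows the mediation diagram: per-SNP effects
``gamma_j`` on the exposure, a mediated path exposure -> mediator -> outcome
with coefficients ``a`` and ``b``, a direct path ``c'``, so the total effect
is ``c = c' + a*b``.  Three disjoint instrument sets are drawn: exposure
instruments (effect ``gamma_j``), mediator instruments (direct mediator
effect ``delta_j``, reaching the outcome only through ``b``), and outcome
instruments (direct outcome effect only) — the latter two are what make
two-step mediation and reverse MR identifiable from the generated data.
Per-SNP truth obeys ``beta_out = c' gamma + b (a gamma + delta) + eta``
where ``eta`` collects directional/balanced pleiotropy on exposure
instruments and the outcome instruments' own effects.

Directional pleiotropy is defined on the exposure-increasing allele:
``eta_j = sign(gamma_j) * Normal(pleio_mean, pleio_sd)``, so a nonzero
``pleio_mean`` is recoverable as an MR-Egger intercept after the
conventional beta_x >= 0 orientation.

Optional block LD: within a block every SNP carries the index SNP's signal
scaled by ``sqrt(ld_r2)`` and appears in the emitted LD table with
``r2 = ld_r2`` (sampling noise is drawn independently per SNP, a
simplification noted in the docs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LdTable
from .sumstats import P_FLOOR, SUMSTATS_COLUMNS, SumstatsTable

_NONPAL_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimParams:
    """Generative parameters of a simulated exposure/mediator/outcome triplet.

    Defaults are the package's reference study conditions: 50 instruments
    per trait, studies of 50 000, per-SNP instrument effects with SD 0.15
    (roughly 1% of trait variance per instrument at intermediate MAF), and
    the planted mediation a=0.4, b=0.5, c'=0.3 (total c=0.5, 40% mediated).
    """

    n_snps: int = 50              # exposure instruments
    n_med_snps: int = 50          # mediator-specific instruments
    n_out_snps: int = 50          # outcome-specific instruments
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_sd: float = 0.15
    a: float = 0.4
    b: float = 0.5
    c_prime: float = 0.3
    pleio_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.8
    palindromic_frac: float = 0.0
    outcome_binary: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("pleio_frac", "palindromic_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) <= 3:
                raise ValueError(f"{name} must be > 3")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must be in [0, 1]")
        if self.gamma_sd < 0 or self.pleio_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def c(self) -> float:
        """Total exposure->outcome effect, c' + a*b."""
        return self.c_prime + self.a * self.b

    @property
    def proportion_pct(self) -> float:
        """True proportion mediated, 100 * a*b / c (NaN for a global null, c = 0)."""
        if self.c == 0:
            return float("nan")
        return 100.0 * self.a * self.b / self.c


@dataclass
class SimTruth:
    """Ground truth of one simulated triplet.

    ``per_snp`` has one row per SNP: role, gamma (effect on exposure),
    delta (direct effect on mediator), eta (direct effect on outcome,
    including pleiotropy), and the implied true per-trait effects.
    """

    a: float
    b: float
    c_prime: float
    c: float
    proportion_pct: float
    per_snp: pd.DataFrame = field(repr=False)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "a": self.a,
            "b": self.b,
            "c_prime": self.c_prime,
            "c": self.c,
            "proportion_pct": self.proportion_pct,
            "seed": self.seed,
            "per_snp": self.per_snp.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        per_snp = pd.DataFrame(payload.pop("per_snp"))
        return cls(per_snp=per_snp, **payload)


def _observed_table(
    rng, trait_id, trait_type, snp_ids, chrom, pos, maf, true_beta, n, alleles, scramble
) -> SumstatsTable:
    """Draw one trait's observed summary statistics around the true effects.

    ``scramble`` re-expresses a random subset of records with swapped
    effect/other alleles (beta sign and eaf flipped) and/or on the opposite
    strand, emulating inconsistent allele coding across source GWAS so that
    harmonization is exercised on every run.
    """
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = true_beta + rng.normal(0.0, se)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), P_FLOOR, 1.0)
    ea = alleles[:, 0].copy()
    oa = alleles[:, 1].copy()
    eaf = maf.copy()
    if scramble:
        swap = rng.random(len(snp_ids)) < 0.5
        beta = np.where(swap, -beta, beta)
        eaf = np.where(swap, 1.0 - eaf, eaf)
        ea, oa = np.where(swap, oa, ea), np.where(swap, ea, oa)
        flip_strand = rng.random(len(snp_ids)) < 0.25
        comp = np.vectorize(_COMPLEMENT.get)
        ea = np.where(flip_strand, comp(ea), ea)
        oa = np.where(flip_strand, comp(oa), oa)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos_bp": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": float(n),
        }
    )
    return SumstatsTable(trait_id, trait_type, df[SUMSTATS_COLUMNS])


def simulate_triplet(
    params: SimParams,
) -> tuple[SumstatsTable, SumstatsTable, SumstatsTable, LdTable, SimTruth]:
    """Simulate exposure, mediator, and outcome GWAS tables plus LD and truth.

    Fully deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)

    # --- exposure instruments, organized into LD blocks on chromosome 1
    n_exp_iv = params.n_snps
    block = params.ld_block_size
    n_blocks = int(np.ceil(n_exp_iv / block))
    block_idx = np.arange(n_exp_iv) // block
    within = np.arange(n_exp_iv) % block
    pos_exp = 1 + block_idx * 25_000_000 + within * 1000
    gamma_index = rng.normal(0.0, params.gamma_sd, size=n_blocks)
    scale = np.where(within == 0, 1.0, np.sqrt(params.ld_r2))
    gamma = gamma_index[block_idx] * scale

    eta_exp = np.zeros(n_exp_iv)
    pleio_mask = rng.random(n_exp_iv) < params.pleio_frac
    n_pleio = int(pleio_mask.sum())
    if n_pleio:
        raw = rng.normal(params.pleio_mean, params.pleio_sd, size=n_pleio)
        eta_exp[pleio_mask] = np.sign(gamma[pleio_mask]) * raw

    # --- mediator- and outcome-specific instruments on chromosomes 2 and 3
    delta_med = rng.normal(0.0, params.gamma_sd, size=params.n_med_snps)
    eta_out = rng.normal(0.0, params.gamma_sd, size=params.n_out_snps)

    n_total = n_exp_iv + params.n_med_snps + params.n_out_snps
    snp_ids = np.array([f"rs{i:05d}" for i in range(1, n_total + 1)])
    chrom = np.concatenate(
        [
            np.repeat("1", n_exp_iv),
            np.repeat("2", params.n_med_snps),
            np.repeat("3", params.n_out_snps),
        ]
    )
    pos = np.concatenate(
        [
            pos_exp,
            1 + np.arange(params.n_med_snps) * 25_000_000,
            1 + np.arange(params.n_out_snps) * 25_000_000,
        ]
    ).astype(np.int64)
    role = np.concatenate(
        [
            np.repeat("exposure_iv", n_exp_iv),
            np.repeat("mediator_iv", params.n_med_snps),
            np.repeat("outcome_iv", params.n_out_snps),
        ]
    )
    gamma_all = np.concatenate([gamma, np.zeros(params.n_med_snps + params.n_out_snps)])
    delta_all = np.concatenate(
        [np.zeros(n_exp_iv), delta_med, np.zeros(params.n_out_snps)]
    )
    eta_all = np.concatenate([eta_exp, np.zeros(params.n_med_snps), eta_out])

    beta_exp_true = gamma_all
    beta_med_true = params.a * gamma_all + delta_all
    beta_out_true = params.c_prime * gamma_all + params.b * beta_med_true + eta_all

    maf = rng.uniform(params.maf_range[0], params.maf_range[1], size=n_total)
    pal = rng.random(n_total) < params.palindromic_frac
    pair_choice = np.where(
        pal,
        rng.integers(0, len(_PAL_PAIRS), size=n_total),
        rng.integers(0, len(_NONPAL_PAIRS), size=n_total),
    )
    alleles = np.array(
        [
            _PAL_PAIRS[c] if is_pal else _NONPAL_PAIRS[c]
            for c, is_pal in zip(pair_choice, pal)
        ]
    )

    exposure = _observed_table(
        rng, "exposure", "quantitative", snp_ids, chrom, pos, maf,
        beta_exp_true, params.n_exp, alleles, scramble=False,
    )
    mediator = _observed_table(
        rng, "mediator", "quantitative", snp_ids, chrom, pos, maf,
        beta_med_true, params.n_med, alleles, scramble=True,
    )
    outcome = _observed_table(
        rng, "outcome", "binary" if params.outcome_binary else "quantitative",
        snp_ids, chrom, pos, maf, beta_out_true, params.n_out, alleles, scramble=True,
    )

    ld = LdTable()
    if block > 1 and params.ld_r2 > 0:
        for b_i in range(n_blocks):
            members = snp_ids[:n_exp_iv][block_idx == b_i]
            for i in range(len(members)):
                for k in range(i + 1, len(members)):
                    ld.add(members[i], members[k], params.ld_r2)

    truth = SimTruth(
        a=params.a,
        b=params.b,
        c_prime=params.c_prime,
        c=params.c,
        proportion_pct=params.proportion_pct,
        per_snp=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "role": role,
                "gamma": gamma_all,
                "delta": delta_all,
                "eta": eta_all,
                "beta_exp_true": beta_exp_true,
                "beta_med_true": beta_med_true,
                "beta_out_true": beta_out_true,
                "maf": maf,
            }
        ),
        seed=params.seed,
    )
    return exposure, mediator, outcome, ld, truth


def spike_outlier(table: SumstatsTable, snp_id: str, shift_in_se: float) -> SumstatsTable:
    """Copy of ``table`` with one SNP's beta shifted by ``shift_in_se * se``.

    Everything else (se, p, alleles) is untouched; useful for planting a
    pleiotropic outlier that the residual-based diagnostics should flag.
    """
    df = table.df.copy()
    hit = df["snp_id"] == snp_id
    if not hit.any():
        raise KeyError(f"unknown snp_id {snp_id!r}")
    df.loc[hit, "beta"] = df.loc[hit, "beta"] + shift_in_se * df.loc[hit, "se"]
    return SumstatsTable(table.trait_id, table.trait_type, df)


def write_triplet(outdir, exposure, mediator, outcome, ld, truth) -> None:
    """Write the standard simulation output directory.

    ``exposure.tsv``, ``mediator.tsv``, ``outcome.tsv``, ``ld.tsv`` and
    ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure.to_tsv(outdir / "exposure.tsv")
    mediator.to_tsv(outdir / "mediator.tsv")
    outcome.to_tsv(outdir / "outcome.tsv")
    ld.to_tsv(outdir / "ld.tsv")
    truth.to_json(outdir / "truth.json")
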