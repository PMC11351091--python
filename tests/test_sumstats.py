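"""Summary-statistics I/O and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmediate.sumstats import (
    GwasRecord,
    HarmonizedSet,
    SumstatsTable,
    harmonize,
    is_palindromic,
    read_sumstats,
)

from conftest import make_table

TSV_HEADER = "rsid\tchr\tbp\tea\toa\tfreq\tb\tstderr\tp\tsamples\n"
COLMAP = {
    "snp_id": "rsid", "chrom": "chr", "pos_bp": "bp",
    "effect_allele": "ea", "other_allele": "oa", "eaf": "freq",
    "beta": "b", "se": "stderr", "pval": "p", "n": "samples",
}


def _write(tmp_path, rows, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(TSV_HEADER + "".join(rows))
    return path


def _row(rsid, ea="A", oa="G", beta="0.1", se="0.02", p="1e-6"):
    return f"{rsid}\t1\t1000\t{ea}\t{oa}\t0.3\t{beta}\t{se}\t{p}\t50000\n"


class TestReadSumstats:
    def test_well_formed_file_loads_every_row(self, tmp_path):
        path = _write(tmp_path, [_row(f"rs{i}") for i in range(5)])
        table = read_sumstats(path, column_map=COLMAP, trait_id="met1")
        assert len(table) == 5
        assert table.trait_id == "met1"
        rec = next(table.records)
        assert rec.snp_id == "rs0" and rec.beta == 0.1 and rec.n == 50000

    def test_invalid_rows_dropped_and_counted(self, tmp_path, caplog):
        rows = [
            _row("rs1"),
            _row("rs2", se="0"),          # non-positive SE
            _row("rs3", oa="AT"),         # indel, not a SNP
            _row("rs4", beta="."),        # missing beta
        ]
        path = _write(tmp_path, rows)
        with caplog.at_level("WARNING"):
            table = read_sumstats(path, column_map=COLMAP)
        assert len(table) == 1
        assert "dropped 3/4" in caplog.text

    def test_missing_pval_filled_from_z(self, tmp_path):
        path = _write(tmp_path, [_row("rs1", p=".")])
        table = read_sumstats(path, column_map=COLMAP)
        rec = next(table.records)
        assert rec.pval == pytest.approx(2 * 2.866515719235352e-07, rel=1e-6)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sumstats(tmp_path / "nope.tsv")

    def test_unmappable_columns_raise(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(ValueError, match="no mappable columns"):
            read_sumstats(path)

    def test_zero_surviving_rows_raise(self, tmp_path):
        path = _write(tmp_path, [_row("rs1", se="0")])
        with pytest.raises(ValueError, match="zero rows"):
            read_sumstats(path, column_map=COLMAP)


@pytest.mark.parametrize(
    "a1, a2, expected",
    [
        ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
        ("A", "G", False), ("A", "C", False), ("C", "T", False), ("G", "T", False),
    ],
)
def test_is_palindromic_definition(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


def test_is_palindromic_rejects_non_acgt():
    with pytest.raises(ValueError):
        is_palindromic("A", "N")
    with pytest.raises(ValueError):
        is_palindromic("A", "A")


def test_gwas_record_invariants():
    kwargs = dict(
        snp_id="rs1", chrom="1", pos_bp=100, effect_allele="A", other_allele="G",
        eaf=0.3, beta=0.1, se=0.02, pval=1e-6, n=1000,
    )
    GwasRecord(**kwargs)  # valid
    for bad in ({"se": 0.0}, {"eaf": 1.2}, {"pval": 0.0}, {"other_allele": "A"}):
        with pytest.raises(ValueError):
            GwasRecord(**{**kwargs, **bad})


def test_duplicate_snp_id_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        make_table(["rs1", "rs1"], beta=0.1, se=0.02)


class TestHarmonize:
    def _exposure(self):
        return make_table(["rs1"], beta=0.5, se=0.05, ea="A", oa="G", eaf=0.2)

    def test_aligned_alleles_pass_through(self):
        outcome = make_table(["rs1"], beta=0.3, se=0.04, ea="A", oa="G", eaf=0.2,
                             trait_id="out")
        h = harmonize(self._exposure(), outcome)
        assert len(h) == 1
        assert h.df.loc[0, "beta_y"] == pytest.approx(0.3)
        assert h.df.loc[0, "eaf_y"] == pytest.approx(0.2)

    def test_swapped_alleles_flip_effect_and_frequency(self):
        outcome = make_table(["rs1"], beta=0.3, se=0.04, ea="G", oa="A", eaf=0.2,
                             trait_id="out")
        h = harmonize(self._exposure(), outcome)
        assert h.df.loc[0, "beta_y"] == pytest.approx(-0.3)
        assert h.df.loc[0, "eaf_y"] == pytest.approx(0.8)

    def test_strand_complement_reconciled(self):
        # exposure A/G; outcome reported on the other strand as T/C
        outcome = make_table(["rs1"], beta=0.3, se=0.04, ea="T", oa="C", eaf=0.2,
                             trait_id="out")
        h = harmonize(self._exposure(), outcome)
        assert len(h) == 1 and h.n_dropped_incompatible == 0
        assert h.df.loc[0, "beta_y"] == pytest.approx(0.3)

    def test_complement_swapped_flips(self):
        outcome = make_table(["rs1"], beta=0.3, se=0.04, ea="C", oa="T", eaf=0.2,
                             trait_id="out")
        h = harmonize(self._exposure(), outcome)
        assert h.df.loc[0, "beta_y"] == pytest.approx(-0.3)

    def test_palindromic_snp_dropped_unconditionally(self):
        exposure = make_table(["rs1"], beta=0.5, se=0.05, ea="A", oa="T")
        outcome = make_table(["rs1"], beta=0.3, se=0.04, ea="A", oa="T",
                             trait_id="out")
        h = harmonize(exposure, outcome)
        assert len(h) == 0
        assert h.n_dropped_palindromic == 1

    def test_irreconcilable_alleles_dropped(self):
        outcome = make_table(["rs1"], beta=0.3, se=0.04, ea="A", oa="C",
                             trait_id="out")
        h = harmonize(self._exposure(), outcome)
        assert len(h) == 0
        assert h.n_dropped_incompatible == 1

    def test_no_overlap_raises(self):
        outcome = make_table(["rs9"], beta=0.3, se=0.04, trait_id="out")
        with pytest.raises(ValueError, match="no overlapping"):
            harmonize(self._exposure(), outcome)

    def test_accounting_identity(self):
        exposure = make_table(
            ["rs1", "rs2", "rs3", "rs4"], beta=0.5, se=0.05,
            ea=np.array(["A", "A", "A", "A"], dtype=object),
            oa=np.array(["G", "T", "G", "G"], dtype=object),
        )
        outcome = make_table(
            ["rs1", "rs2", "rs3", "rs5"], beta=0.3, se=0.04,
            ea=np.array(["A", "A", "A", "A"], dtype=object),
            oa=np.array(["G", "T", "C", "G"], dtype=object),
            trait_id="out",
        )
        h = harmonize(exposure, outcome)
        overlap = 3  # rs1 ok, rs2 palindromic, rs3 incompatible
        assert len(h) + h.n_dropped_palindromic + h.n_dropped_incompatible == overlap

    def test_orientation_alignment_is_idempotent(self, default_triplet):
        exposure, mediator, _, _, _ = default_triplet
        h1 = harmonize(exposure, mediator)
        # rebuild the outcome side already expressed on the exposure orientation
        ex = exposure.df.set_index("snp_id")
        rows = h1.df.copy()
        aligned = pd.DataFrame(
            {
                "snp_id": rows["snp_id"],
                "chrom": rows["chrom"],
                "pos_bp": rows["pos_bp"],
                "effect_allele": ex.loc[rows["snp_id"], "effect_allele"].to_numpy(),
                "other_allele": ex.loc[rows["snp_id"], "other_allele"].to_numpy(),
                "eaf": rows["eaf_y"].to_numpy(),
                "beta": rows["beta_y"].to_numpy(),
                "se": rows["se_y"].to_numpy(),
                "pval": 0.5,
                "n": rows["n_y"].to_numpy(),
            }
        )
        mediator2 = SumstatsTable("mediator", "quantitative", aligned)
        h2 = harmonize(exposure, mediator2)
        merged = h1.df.merge(h2.df, on="snp_id", suffixes=("_1", "_2"))
        assert len(merged) == len(h1)
        np.testing.assert_allclose(merged["beta_y_1"], merged["beta_y_2"])
        np.testing.assert_allclose(merged["eaf_y_1"], merged["eaf_y_2"])

    @given(st.randoms(use_true_random=False))
    def test_row_order_invariance(self, rnd):
        ids = [f"rs{i}" for i in range(8)]
        exposure = make_table(ids, beta=0.4, se=0.05)
        perm = list(range(8))
        rnd.shuffle(perm)
        out_df = make_table(ids, beta=0.2, se=0.04, trait_id="out").df.iloc[perm]
        outcome = SumstatsTable("out", "quantitative", out_df)
        h = harmonize(exposure, outcome)
        assert sorted(h.df["snp_id"]) == sorted(ids)

    def test_harmonized_set_requires_positive_ses(self):
        df = harmonize(
            self._exposure(),
            make_table(["rs1"], beta=0.3, se=0.04, ea="A", oa="G", trait_id="out"),
        ).df.copy()
        df.loc[0, "se_y"] = 0.0
        with pytest.raises(ValueError, match="positive standard errors"):
            HarmonizedSet("x", "y", df)
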