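import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logoscan import gwas_io
from logoscan.gwas_io import (
    BlockSpec,
    FormatError,
    InputError,
    RegionRecord,
    assign_blocks,
    harmonize_pair,
    is_strand_ambiguous,
    read_blocks,
    read_regions,
    read_sumstats,
    write_regions,
)


def write_ss(path, rows, header="SNP\tA1\tA2\tZ\tN"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


class TestReadSumstats:
    def test_identity_parse(self, tmp_path):
        p = write_ss(tmp_path / "a.sumstats", [
            "rs1\tA\tG\t1.5\t1000",
            "rs2\tC\tT\t-0.3\t1000",
            "rs3\tG\tA\t0.0\t1000",
        ])
        ss = read_sumstats(p)
        assert len(ss) == 3
        assert ss.n_dropped == 0
        np.testing.assert_allclose(ss.z, [1.5, -0.3, 0.0])

    def test_na_z_dropped(self, tmp_path):
        p = write_ss(tmp_path / "a.sumstats", [
            "rs1\tA\tG\t1.5\t1000",
            "rs2\tC\tT\tNA\t1000",
        ])
        ss = read_sumstats(p)
        assert len(ss) == 1
        assert ss.n_dropped == 1

    def test_duplicate_snp_keeps_first(self, tmp_path):
        # oracle: independent line-by-line scan keeping first occurrences
        lines = [
            "rs1\tA\tG\t1.0\t1000",
            "rs2\tC\tT\t2.0\t1000",
            "rs1\tA\tG\t9.0\t1000",
            "rs3\tG\tC\t3.0\t1000",
        ]
        seen, expect = set(), []
        for ln in lines:
            sid, _, _, z, _ = ln.split("\t")
            if sid not in seen:
                seen.add(sid)
                expect.append((sid, float(z)))
        p = write_ss(tmp_path / "a.sumstats", lines)
        ss = read_sumstats(p)
        assert len(ss) == len(lines) - 1
        assert list(zip(ss.snp, ss.z)) == expect

    def test_missing_column_named(self, tmp_path):
        p = write_ss(tmp_path / "a.sumstats", ["rs1\tA\tG\t1.5"], header="SNP\tA1\tA2\tZ")
        with pytest.raises(FormatError, match="N"):
            read_sumstats(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.sumstats"
        p.write_text("")
        with pytest.raises(InputError):
            read_sumstats(p)

    def test_column_map(self, tmp_path):
        p = write_ss(tmp_path / "a.sumstats", ["rs1\tA\tG\t1.5\t1000"],
                     header="rsid\tA1\tA2\tZ\tN")
        ss = read_sumstats(p, column_map={"SNP": "rsid"})
        assert list(ss.snp) == ["rs1"]


def make_ss(snp, a1, a2, z, n=1000.0):
    return gwas_io.SumStats(df=pd.DataFrame({
        "snp": snp, "a1": a1, "a2": a2,
        "z": np.asarray(z, dtype=float), "n": float(n),
    }))


def make_panel_meta(snp, a1, a2, pos=None, chrom="1"):
    if pos is None:
        pos = np.arange(1, len(snp) + 1) * 1000
    return pd.DataFrame({"snp": snp, "chrom": chrom, "pos": pos, "a1": a1, "a2": a2})


class TestHarmonizePair:
    def test_identical_alleles_keep_z(self):
        s1 = make_ss(["rs1"], ["A"], ["G"], [0.7])
        s2 = make_ss(["rs1"], ["A"], ["G"], [1.3])
        hp = harmonize_pair(s1, s2, make_panel_meta(["rs1"], ["A"], ["G"]))
        assert hp.z2[0] == 1.3

    def test_swapped_alleles_flip_sign(self):
        s1 = make_ss(["rs1"], ["A"], ["G"], [0.7])
        s2 = make_ss(["rs1"], ["G"], ["A"], [1.3])
        hp = harmonize_pair(s1, s2, make_panel_meta(["rs1"], ["A"], ["G"]))
        assert hp.z2[0] == -1.3

    def test_ambiguous_removed(self):
        s1 = make_ss(["rs1", "rs2"], ["A", "A"], ["T", "G"], [1.0, 2.0])
        s2 = make_ss(["rs1", "rs2"], ["A", "A"], ["T", "G"], [1.0, 2.0])
        hp = harmonize_pair(s1, s2, make_panel_meta(["rs1", "rs2"], ["A", "A"], ["T", "G"]))
        assert list(hp.snp) == ["rs2"]

    def test_mismatch_dropped(self):
        s1 = make_ss(["rs1", "rs2"], ["A", "C"], ["G", "T"], [1.0, 2.0])
        s2 = make_ss(["rs1", "rs2"], ["A", "C"], ["C", "T"], [1.0, 2.0])
        hp = harmonize_pair(s1, s2, make_panel_meta(["rs1", "rs2"], ["A", "C"], ["G", "T"]))
        assert list(hp.snp) == ["rs2"]

    def test_empty_intersection(self):
        s1 = make_ss(["rs1"], ["A"], ["G"], [1.0])
        s2 = make_ss(["rs2"], ["A"], ["G"], [1.0])
        with pytest.raises(InputError):
            harmonize_pair(s1, s2, make_panel_meta(["rs1", "rs2"], ["A", "A"], ["G", "G"]))

    def test_idempotent(self):
        s1 = make_ss(["rs1", "rs2"], ["A", "C"], ["G", "T"], [1.0, -0.5])
        s2 = make_ss(["rs1", "rs2"], ["G", "C"], ["A", "T"], [1.3, 0.4])
        meta = make_panel_meta(["rs1", "rs2"], ["A", "C"], ["G", "T"])
        hp1 = harmonize_pair(s1, s2, meta)
        s1b = make_ss(hp1.snp, hp1.df["a1"], hp1.df["a2"], hp1.z1)
        s2b = make_ss(hp1.snp, hp1.df["a1"], hp1.df["a2"], hp1.z2)
        hp2 = harmonize_pair(s1b, s2b, meta)
        np.testing.assert_array_equal(hp1.z1, hp2.z1)
        np.testing.assert_array_equal(hp1.z2, hp2.z2)

    def test_output_snps_in_panel(self):
        meta = make_panel_meta(["rs1", "rs2"], ["A", "C"], ["G", "T"])
        s1 = make_ss(["rs1", "rs2", "rs3"], ["A", "C", "A"], ["G", "T", "G"], [1, 2, 3])
        s2 = make_ss(["rs1", "rs2", "rs3"], ["A", "C", "A"], ["G", "T", "G"], [1, 2, 3])
        hp = harmonize_pair(s1, s2, meta)
        assert set(hp.snp) <= set(meta["snp"])

    def test_maf_filter(self):
        meta = make_panel_meta(["rs1", "rs2"], ["A", "A"], ["G", "G"])
        meta["maf"] = [0.005, 0.3]
        s = make_ss(["rs1", "rs2"], ["A", "A"], ["G", "G"], [1.0, 2.0])
        hp = harmonize_pair(s, s, meta, maf_min=0.01)
        assert list(hp.snp) == ["rs2"]

    def test_sorted_by_position(self):
        meta = make_panel_meta(["rs1", "rs2"], ["A", "C"], ["G", "T"], pos=[5000, 100])
        s = make_ss(["rs1", "rs2"], ["A", "C"], ["G", "T"], [1.0, 2.0])
        hp = harmonize_pair(s, s, meta)
        assert list(hp.pos) == [100, 5000]


@given(z=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=20))
@settings(max_examples=25, deadline=None)
def test_double_flip_restores_z(z):
    # flipping alleles twice restores the original z vector exactly
    z = np.asarray(z)
    snp = [f"rs{i}" for i in range(len(z))]
    meta = make_panel_meta(snp, ["A"] * len(z), ["G"] * len(z))
    s1 = make_ss(snp, ["A"] * len(z), ["G"] * len(z), np.ones(len(z)))
    s2_flipped = make_ss(snp, ["G"] * len(z), ["A"] * len(z), -z)
    hp = harmonize_pair(s1, s2_flipped, meta)
    np.testing.assert_array_equal(hp.z2, z)


class TestBlocks:
    def test_single_block(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t0\t1000000\n")
        blocks = read_blocks(p)
        assert len(blocks) == 1
        assert blocks[0] == BlockSpec("chr1", 0, 1000000, 0)

    def test_half_open_assignment(self, tmp_path):
        # SNP at 1-based pos 1,000,000 -> 0-based 999,999 -> first block
        p = tmp_path / "b.bed"
        p.write_text("chr1\t0\t1000000\nchr1\t1000000\t2000000\n")
        blocks = read_blocks(p)
        ids = assign_blocks(["chr1", "chr1"], [1_000_000, 1_000_001], blocks)
        assert list(ids) == [0, 1]

    def test_overlap_error(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t0\t1000\nchr1\t500\t2000\n")
        with pytest.raises(InputError, match="overlap"):
            read_blocks(p)

    def test_outside_blocks(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t0\t1000\n")
        ids = assign_blocks(["chr1", "chr2"], [2000, 500], read_blocks(p))
        assert list(ids) == [-1, -1]


class TestRegions:
    def regions(self):
        return [
            RegionRecord("chr2", 500, 900, 3, 12, -2.5, 0.01, 0.04),
            RegionRecord("chr1", 100, 200, 1, 10, 3.25, 0.002, 0.01),
        ]

    def test_empty_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_regions([], p)
        assert p.read_text().strip() == "\t".join(
            ("chrom", "start", "end", "block_id", "n_snps", "q_stat", "p", "q_fdr")
        )

    def test_sorted_output(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_regions(self.regions(), p)
        lines = p.read_text().strip().split("\n")
        assert lines[1].startswith("chr1") and lines[2].startswith("chr2")

    def test_round_trip(self, tmp_path):
        p = tmp_path / "r.tsv"
        regions = self.regions()
        write_regions(regions, p)
        back = read_regions(p)
        by_chrom = {r.chrom: r for r in back}
        for r in regions:
            b = by_chrom[r.chrom]
            assert (b.start_bp, b.end_bp, b.block_id, b.n_snps) == (
                r.start_bp, r.end_bp, r.block_id, r.n_snps)
            assert b.q_stat == pytest.approx(r.q_stat)
            assert b.p == pytest.approx(r.p)
            assert b.q_fdr == pytest.approx(r.q_fdr)


class TestPanelIO:
    def test_dosage_tsv_round_trip(self, tmp_path, rng):
        raw = rng.binomial(2, 0.4, size=(6, 4)).astype(float)
        raw[0, 0] = np.nan
        meta = make_panel_meta([f"rs{i}" for i in range(4)], ["A"] * 4, ["G"] * 4)
        p = tmp_path / "panel.tsv"
        gwas_io.write_dosage_tsv(raw, meta, p)
        back, meta2 = gwas_io.read_dosage_tsv(p)
        np.testing.assert_allclose(back, raw)
        assert list(meta2["snp"]) == list(meta["snp"])

    def test_plink_bed_round_trip(self, tmp_path, rng):
        # write a tiny SNP-major bed by hand, read it back
        n, m = 5, 3
        doses = rng.integers(0, 3, size=(n, m)).astype(float)
        doses[2, 1] = np.nan
        code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
        body = bytearray([0x6C, 0x1B, 0x01])
        for j in range(m):
            byte, filled = 0, 0
            for i in range(n):
                c = 0b01 if np.isnan(doses[i, j]) else code[doses[i, j]]
                byte |= c << (2 * filled)
                filled += 1
                if filled == 4:
                    body.append(byte)
                    byte, filled = 0, 0
            if filled:
                body.append(byte)
        prefix = tmp_path / "toy"
        (tmp_path / "toy.bed").write_bytes(bytes(body))
        (tmp_path / "toy.bim").write_text(
            "".join(f"1\trs{j}\t0\t{1000 * (j + 1)}\tA\tG\n" for j in range(m))
        )
        (tmp_path / "toy.fam").write_text(
            "".join(f"f{i}\ti{i}\t0\t0\t1\t-9\n" for i in range(n))
        )
        got, bim = gwas_io.read_bed(prefix)
        np.testing.assert_allclose(got, doses)
        assert list(bim["snp"]) == ["rs0", "rs1", "rs2"]


def test_is_strand_ambiguous():
    amb = is_strand_ambiguous(["A", "C", "A"], ["T", "G", "G"])
    assert list(amb) == [True, True, False]
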