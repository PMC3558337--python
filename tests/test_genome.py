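"""Coordinate arithmetic, census, partition accounting, and annotation I/O."""

import warnings

import pytest
from hypothesis import given, strategies as st

import mitocomp as mc
from mitocomp.genome import CoordinateError, rotate_table


class TestFeatureLength:
    @pytest.mark.parametrize("start,end,L,expected", [
        (1, 1563, None, 1563),      # full-size first gene
        (5, 5, None, 1),            # single base
        (9, 2, 10, 4),              # wraps the origin
        (1, 10, 10, 10),
    ])
    def test_examples(self, start, end, L, expected):
        f = mc.GeneFeature("cox1", "PCG", start, end)
        assert mc.feature_length(f, L) == expected

    def test_wrap_needs_genome_length(self):
        f = mc.GeneFeature("cox1", "PCG", 9, 2)
        with pytest.raises(CoordinateError):
            mc.feature_length(f)

    def test_wrap_outside_genome(self):
        f = mc.GeneFeature("cox1", "PCG", 12, 2)
        with pytest.raises(CoordinateError):
            mc.feature_length(f, 10)


class TestSubsequence:
    def test_plain(self):
        g = mc.CircularGenome("g", "ACGT")
        assert g.subsequence(2, 3) == "CG"

    def test_wrap(self):
        g = mc.CircularGenome("g", "ACGT")
        assert g.subsequence(4, 1) == "TA"

    def test_full_span_identity(self):
        g = mc.CircularGenome("g", "ACGTACGTAC")
        assert g.subsequence(1, g.length) == g.residues

    def test_out_of_range(self):
        g = mc.CircularGenome("g", "ACGT")
        with pytest.raises(CoordinateError):
            g.subsequence(0, 3)
        with pytest.raises(CoordinateError):
            g.subsequence(1, 5)

    def test_wrap_on_linear_rejected(self):
        g = mc.CircularGenome("g", "ACGT", topology="linear")
        with pytest.raises(CoordinateError):
            g.subsequence(3, 2)

    @given(st.data())
    def test_length_consistency_with_feature_length(self, data):
        """|subsequence(s, e)| always equals feature_length((s, e), L)."""
        n = data.draw(st.integers(10, 200))
        residues = "".join(data.draw(st.sampled_from("ACGTN")) for _ in range(n))
        g = mc.CircularGenome("g", residues)
        s = data.draw(st.integers(1, n))
        e = data.draw(st.integers(1, n))
        f = mc.GeneFeature("cox1", "PCG", s, e)
        assert len(g.subsequence(s, e)) == mc.feature_length(f, n)


class TestCensus:
    def test_bx_intergenic_census(self, bx_table):
        census = mc.gap_overlap_census(bx_table, 14778)
        gaps = sorted(e.length for e in census if e.length > 0)
        assert len(gaps) == 9
        assert gaps[0] == 1 and gaps[-1] == 1650
        by_left = {e.left_gene: e.length for e in census}
        assert by_left["cox2"] == -2          # two shared bases with trnH
        assert by_left["nad1"] == -5          # five shared bases with atp6

    def test_pv_intergenic_census(self, pv_table):
        census = mc.gap_overlap_census(pv_table, 21656)
        gaps = [e.length for e in census if e.length > 0]
        assert len(gaps) == 24
        assert sum(gaps) == 8821
        junction = next(e for e in census if e.left_gene == "trnE")
        assert junction.right_gene == "cox1" and junction.length == 11
        assert not any(e.length < 0 for e in census)

    def test_duplicate_coordinates_rejected(self):
        feats = [mc.GeneFeature("cox1", "PCG", 1, 12, "+", "ATT", "TAA"),
                 mc.GeneFeature("cox2", "PCG", 1, 12, "+", "ATT", "TAA")]
        with pytest.raises(ValueError, match="duplicate"):
            mc.gap_overlap_census(mc.FeatureTable("g", feats), 100)

    @pytest.mark.parametrize("offset", [1, 1000, 7389, 14000])
    def test_rotation_invariance(self, bx_table, offset):
        """Rotating the origin never changes the gap/overlap multiset."""
        base = sorted(e.length for e in mc.gap_overlap_census(bx_table, 14778))
        rotated = rotate_table(bx_table, offset, 14778)
        moved = sorted(e.length for e in mc.gap_overlap_census(rotated, 14778))
        assert moved == base


class TestPartitionReport:
    def test_bx_accounting(self, bx_table):
        rep = mc.partition_report(bx_table, genome_length=14778)
        assert rep.pcg_coding_total == 10182
        assert rep.total_codons == 3394
        assert rep.rrna_total == 1648
        assert rep.trna_total == 1214
        assert rep.ncr_feature_total == 1650
        assert rep.reconciles and rep.diagnostic is None

    def test_pv_accounting(self, pv_table):
        rep = mc.partition_report(pv_table, genome_length=21656)
        assert rep.pcg_coding_total == 10002
        assert rep.total_codons == 3334
        assert rep.rrna_total == 1581
        assert rep.trna_total == 1216
        assert rep.intergenic_total == 8821
        assert rep.reconciles

    def test_overlap_free_conservation(self):
        """Without overlaps, spans plus gaps tile the circle exactly."""
        spec = mc.GenomeSpec.random(seed=11, overlap_prob=0.0)
        table = mc.FeatureTable(spec.genome_id, spec.features)
        rep = mc.partition_report(table, genome_length=spec.length)
        assert rep.overlap_total == 0
        assert (rep.pcg_span_total + rep.rrna_total + rep.trna_total
                + rep.intergenic_total == spec.length)

    def test_reconciliation_failure_is_diagnosed(self, bx_table):
        """A genome length shorter than the annotation is a structured
        diagnostic, not an exception."""
        rep = mc.partition_report(bx_table, genome_length=14000)
        assert not rep.reconciles
        assert "NCR" in rep.diagnostic or "nad4" in rep.diagnostic

    def test_incomplete_table_rejected(self, bx_table):
        feats = [f for f in bx_table.features if f.name != "cox3"]
        with pytest.raises(ValueError, match="cox3"):
            mc.partition_report(mc.FeatureTable("bx", feats), genome_length=14778)

    @pytest.mark.parametrize("seed", range(25))
    def test_reconciliation_on_random_layouts(self, seed):
        spec = mc.GenomeSpec.random(seed)
        rep = mc.partition_report(mc.FeatureTable(spec.genome_id, spec.features),
                                  genome_length=spec.length)
        assert rep.reconciles, rep.diagnostic


class TestIO:
    def test_tsv_round_trip(self, bx_table, tmp_path):
        p = tmp_path / "bx.tsv"
        mc.write_table_tsv(bx_table, p)
        back = mc.read_table_tsv(p, genome_id=bx_table.genome_id)
        assert back.features == bx_table.features

    def test_gff3_round_trip(self, pv_table, tmp_path):
        p = tmp_path / "pv.gff3"
        mc.write_gff3(pv_table, p)
        back = mc.read_gff3(p)
        assert back.features == pv_table.features
        assert back.genome_id == pv_table.genome_id

    def test_wrapping_feature_preserved(self, tmp_path):
        feats = [mc.GeneFeature("cox1", "PCG", 90, 20, "+", "ATT", "TAA")]
        t = mc.FeatureTable("wrapper", feats)
        p = tmp_path / "wrap.tsv"
        mc.write_table_tsv(t, p)
        assert mc.read_table_tsv(p).features == feats

    def test_gff3_zero_coordinate_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\ng\tx\tgene\t0\t10\t.\t+\t.\tID=cox1;gene_class=PCG\n")
        with pytest.raises(mc.io.ParseError, match="1-based"):
            mc.read_gff3(p)

    def test_unknown_gene_name_warns_not_fails(self, tmp_path):
        p = tmp_path / "odd.tsv"
        p.write_text("atp8\tPCG\t1\t99\t+\tATG\tTAA\n")
        with pytest.warns(UserWarning, match="atp8"):
            t = mc.read_table_tsv(p)
        assert t.features[0].name == "atp8"

    def test_fasta_round_trip(self, tmp_path):
        g = mc.CircularGenome("gx", "ACGTN" * 10)
        p = tmp_path / "g.fa"
        mc.write_genome(g, p)
        back = mc.read_genome(p)
        assert back.residues == g.residues and back.id == "gx"
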