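"""Translation, alignment, back-translation, and supermatrix assembly."""

import numpy as np
import pytest

import mitocomp as mc
from mitocomp.phylo import DEFAULT_ALIGN, GAP
from oracles import exhaustive_alignment_score


class TestTranslatePcg:
    def test_trivial(self, code):
        g = mc.CircularGenome("g", "ATGAAATAA")
        f = mc.GeneFeature("cox1", "PCG", 1, 9, "+", "ATG", "TAA")
        assert mc.translate_pcg(f, g) == "MK"

    def test_complete_stop_gene_length(self, bx_synth):
        genome, table, _ = bx_synth
        aa = mc.translate_pcg(table.by_name("nad4L"), genome)
        assert len(aa) == (234 - 3) // 3 == 77

    def test_incomplete_stop_contributes_no_residue(self, bx_synth):
        genome, table, _ = bx_synth
        aa = mc.translate_pcg(table.by_name("atp6"), genome)
        assert len(aa) == (595 - 1) // 3 == 198

    def test_internal_stop_is_error(self):
        g = mc.CircularGenome("g", "ATGTAAAAATAA")
        f = mc.GeneFeature("cox1", "PCG", 1, 12, "+")
        with pytest.raises(ValueError, match="internal stop"):
            mc.translate_pcg(f, g)


class TestStripStop:
    @pytest.mark.parametrize("cds,expected", [
        ("ATGAAATAA", "ATGAAA"),
        ("ATGAAATAG", "ATGAAA"),
        ("ATGAAAT", "ATGAAA"),
        ("ATGAAATA", "ATGAAA"),
        ("ATGAAA", "ATGAAA"),
    ])
    def test_variants(self, cds, expected):
        assert mc.strip_stop(cds) == expected

    def test_frameshifted_tail_rejected(self):
        with pytest.raises(ValueError):
            mc.strip_stop("ATGAAAG")


class TestPairwiseAlignment:
    def test_one_gap_column(self):
        ra, rb, score = mc.needleman_wunsch("MKV", "MV")
        assert (ra, rb) == ("MKV", "M-V")
        assert score == exhaustive_alignment_score(
            "MKV", "MV", DEFAULT_ALIGN.match, DEFAULT_ALIGN.mismatch,
            DEFAULT_ALIGN.gap_open, DEFAULT_ALIGN.gap_extend)

    def test_identical_sequences_align_gap_free(self):
        ra, rb, _ = mc.needleman_wunsch("MKVLW", "MKVLW")
        assert ra == rb == "MKVLW"

    @pytest.mark.parametrize("seed", range(12))
    def test_score_equals_exhaustive_oracle(self, seed):
        """DP scores equal brute-force enumeration over all alignments for
        short inputs."""
        rng = np.random.default_rng(seed)
        alpha = "MKVLWFINS"
        a = "".join(rng.choice(list(alpha), size=rng.integers(1, 8)))
        b = "".join(rng.choice(list(alpha), size=rng.integers(1, 8)))
        _, _, score = mc.needleman_wunsch(a, b)
        assert score == exhaustive_alignment_score(
            a, b, DEFAULT_ALIGN.match, DEFAULT_ALIGN.mismatch,
            DEFAULT_ALIGN.gap_open, DEFAULT_ALIGN.gap_extend)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mc.needleman_wunsch("", "MK")


class TestMultipleAlignment:
    def test_identical_sequences_gap_free(self):
        pa = mc.align_proteins({"a": "MKVL", "b": "MKVL", "c": "MKVL"})
        assert pa.rows == ("MKVL",) * 3

    @pytest.mark.parametrize("seed", range(8))
    def test_degapping_recovers_inputs(self, seed):
        rng = np.random.default_rng(seed)
        alpha = list("MKVLWFINSGTA")
        base = "".join(rng.choice(alpha, size=30))
        seqs = {}
        for t in ("t1", "t2", "t3", "t4"):
            s = list(base)
            for _ in range(int(rng.integers(0, 6))):       # substitutions
                s[int(rng.integers(len(s)))] = str(rng.choice(alpha))
            if rng.random() < 0.5 and len(s) > 5:          # deletion
                k = int(rng.integers(1, 4))
                p = int(rng.integers(0, len(s) - k))
                del s[p:p + k]
            seqs[t] = "".join(s)
        pa = mc.align_proteins(seqs)
        for t, original in seqs.items():
            assert pa.degapped(t) == original


class TestBacktranslate:
    def test_gap_becomes_triple_dash(self):
        pa = mc.ProteinAlignment(("x", "y"), ("M-K", "MGK"))
        ca = mc.backtranslate(pa, {"x": "ATGAAATAA", "y": "ATGGGAAAA"})
        assert ca.rows == ("ATG---AAA", "ATGGGAAAA")
        assert ca.n_columns == 3 * pa.n_columns

    def test_translation_mismatch_rejected(self):
        pa = mc.ProteinAlignment(("x",), ("MK",))
        with pytest.raises(ValueError, match="does not match"):
            mc.backtranslate(pa, {"x": "ATGGGA"})

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_over_random_gene_sets(self, seed, code):
        """Degapping a back-translated row recovers the stop-stripped CDS."""
        rng = np.random.default_rng(seed)
        sense = [c for c in mc.codes.ALL_CODONS if not code.is_stop(c)]
        cds = {}
        for t in ("t1", "t2", "t3"):
            n = int(rng.integers(10, 40))
            cds[t] = "".join(rng.choice(sense, size=n)) + str(rng.choice(["TAA", "TAG", "T", "TA"]))
        proteins = {t: code.translate(mc.strip_stop(s)) for t, s in cds.items()}
        pa = mc.align_proteins(proteins)
        ca = mc.backtranslate(pa, cds)
        for t, s in cds.items():
            assert ca.degapped(t) == mc.strip_stop(s)


class TestSupermatrix:
    def _aln(self, gene, width, taxa=("t1", "t2")):
        rng = np.random.default_rng(sum(map(ord, gene)))
        rows = tuple("".join(rng.choice(list("ACGT"), size=width)) for _ in taxa)
        return mc.CodonAlignment(taxa, rows, gene=gene)

    def test_two_gene_concatenation(self):
        sm = mc.concatenate([self._aln("cox1", 6), self._aln("atp6", 6)])
        assert sm.n_columns == 12
        assert sm.partitions == (("atp6", 1, 6), ("cox1", 7, 12))

    def test_partitions_tile_without_overlap(self):
        sm = mc.concatenate([self._aln(g, 9) for g in ("nad1", "cob", "cox2")])
        covered = []
        for _, s, e in sm.partitions:
            covered.extend(range(s, e + 1))
        assert covered == list(range(1, sm.n_columns + 1))

    def test_missing_taxon_needs_fill_flag(self):
        a = self._aln("cox1", 6)
        b = self._aln("cox2", 6, taxa=("t1", "t3"))
        with pytest.raises(ValueError, match="fill_missing"):
            mc.concatenate([a, b])
        sm = mc.concatenate([a, b], fill_missing=True)
        assert set(sm.taxa) == {"t1", "t2", "t3"}
        assert sm.row("t3")[6:12].count(GAP) == 0 and sm.row("t3")[:6] == GAP * 6

    def test_protein_supermatrix_backtranslates_3x(self):
        """A 3,928-column protein matrix maps to 11,784 nucleotide columns,
        and third-position exclusion leaves 7,856."""
        widths = [328] * 11 + [320]
        assert sum(widths) == 3928
        alns = [self._aln(g, 3 * w) for g, w in zip(mc.PCG_GENES, widths)]
        sm = mc.concatenate(alns)
        assert sm.n_columns == 11784
        assert mc.exclude_third_positions(sm).n_columns == 7856

    def test_exclude_third_minimal(self):
        sm = mc.concatenate([self._aln("cox1", 3)])
        out = mc.exclude_third_positions(sm)
        assert out.n_columns == 2
        assert out.rows[0] == sm.rows[0][:2]

    def test_excluded_and_kept_columns_reconstruct_input(self):
        sm = mc.concatenate([self._aln("cox1", 9), self._aln("nad3", 6)])
        kept = mc.exclude_third_positions(sm)
        for row_in, row_kept in zip(sm.rows, kept.rows):
            thirds = "".join(row_in[i] for i in range(2, len(row_in), 3))
            rebuilt = []
            k = iter(row_kept)
            t = iter(thirds)
            for i in range(len(row_in)):
                rebuilt.append(next(t) if i % 3 == 2 else next(k))
            assert "".join(rebuilt) == row_in

    def test_exclusion_commutes_with_concatenation(self):
        alns = [self._aln("cox1", 9), self._aln("nad3", 6)]
        a = mc.exclude_third_positions(mc.concatenate(alns))
        per_gene = [mc.exclude_third_positions(mc.concatenate([x])) for x in alns]
        b_rows = tuple("".join(p.rows[i] for p in sorted(per_gene, key=lambda s: s.partitions[0][0]))
                       for i in range(2))
        assert a.rows == b_rows

    def test_writers_smoke(self, tmp_path):
        sm = mc.concatenate([self._aln("cox1", 6), self._aln("cob", 6)])
        mc.write_phylip_relaxed(sm, tmp_path / "m.phy")
        mc.write_nexus(sm, tmp_path / "m.nex")
        mc.write_raxml_partitions(sm, tmp_path / "m.part")
        phy = (tmp_path / "m.phy").read_text().splitlines()
        assert phy[0].split() == ["2", "12"]
        nex = (tmp_path / "m.nex").read_text()
        assert "charset cob = 1-6;" in nex and "charset cox1 = 7-12;" in nex
        part = (tmp_path / "m.part").read_text()
        assert "DNA, cob = 1-6" in part
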