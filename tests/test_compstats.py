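"""Composition profiles, codon usage, and the published-table consistency
suite."""

import random

import pytest
from scipy import stats

import mitocomp as mc
from mitocomp.compstats import CodonUsageTable
from mitocomp.simulate import _at_background
import numpy as np


class TestBaseComposition:
    def test_all_t(self):
        p = mc.base_composition("TTTT")
        assert p.rounded() == {"A": 0.0, "C": 0.0, "G": 0.0, "T": 100.0, "AT": 100.0}

    def test_uniform(self):
        p = mc.base_composition("ACGT")
        assert p.rounded() == {"A": 25.0, "C": 25.0, "G": 25.0, "T": 25.0, "AT": 50.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mc.base_composition("")

    def test_n_excluded_from_denominator(self):
        p = mc.base_composition("AANN")
        assert p.percent("A") == 100.0 and p.length == 4

    def test_permutation_invariance(self):
        seq = "ACGTTTGACCA" * 30
        shuffled = "".join(random.Random(0).sample(seq, len(seq)))
        assert mc.base_composition(seq).rounded() == mc.base_composition(shuffled).rounded()

    def test_iid_background_hits_at_target(self):
        """14.8 kb of background drawn at an 83.5% A+T target lands within
        half a percent (binomial sampling bound)."""
        seq = "".join(_at_background(np.random.default_rng(0), 14778, 0.835))
        assert abs(mc.base_composition(seq).at_percent - 83.5) < 0.5


class TestPartitionedComposition:
    def test_partition_lengths_bx(self, bx_synth):
        genome, table, _ = bx_synth
        profs = {p.partition: p for p in mc.partitioned_composition(genome, table)}
        assert profs["Entire sequence"].length == 14778
        assert profs["Protein coding sequence"].length == 10182
        assert profs["1st"].length == profs["2nd"].length == profs["3rd"].length == 3394
        assert profs["Ribosomal RNA gene sequence"].length == 1648
        assert profs["Transfer RNA gene sequence"].length == 1214
        assert profs["Non coding region"].length == 1650

    def test_codon_position_length_equals_codon_total(self, pv_synth):
        genome, table, _ = pv_synth
        profs = {p.partition: p for p in mc.partitioned_composition(genome, table)}
        usage = mc.codon_usage(genome, table)
        assert profs["1st"].length == usage.total_codons == 3334

    def test_ncr_at_target_reached(self, bx_synth):
        """The synthetic non-coding region hits its extreme A+T target
        within one percent."""
        genome, table, _ = bx_synth
        profs = {p.partition: p for p in mc.partitioned_composition(genome, table)}
        assert abs(profs["Non coding region"].at_percent - 98.7) < 1.0

    def test_include_stops_restores_span_total(self, bx_synth):
        genome, table, _ = bx_synth
        profs = {p.partition: p for p in
                 mc.partitioned_composition(genome, table, include_stops=True)}
        rep = mc.partition_report(table, genome)
        assert profs["Protein coding sequence"].length == rep.pcg_span_total == 10214


class TestCodonUsage:
    def test_single_gene(self):
        g = mc.CircularGenome("g", "ATGAAATAA" + "ATGAAATAA" * 11)
        feats = [mc.GeneFeature(n, "PCG", 1 + 9 * i, 9 * (i + 1), "+", "ATG", "TAA")
                 for i, n in enumerate(mc.PCG_GENES)]
        u = mc.codon_usage(g, mc.FeatureTable("g", feats))
        assert u.count("ATG") == 12 and u.count("AAA") == 12
        assert u.total_codons == 24
        assert u.count("TAA") == 0

    def test_cross_check_with_partition(self, bx_synth):
        """Codon total x 3 equals the stop-excluded coding partition."""
        genome, table, _ = bx_synth
        u = mc.codon_usage(genome, table)
        rep = mc.partition_report(table, genome)
        assert u.total_codons * 3 == rep.pcg_coding_total

    def test_generator_codon_distribution_recovered(self, bx_synth):
        """Observed codon frequencies sit inside Bonferroni-adjusted 99%
        binomial intervals around the generative distribution."""
        genome, table, truth = bx_synth
        u = mc.codon_usage(genome, table)
        n = u.total_codons
        dist = truth["codon_distribution"]
        sense = [c for c, p in dist.items() if p > 0]
        alpha = 0.01 / len(sense)
        for c in sense:
            lo = stats.binom.ppf(alpha / 2, n, dist[c])
            hi = stats.binom.ppf(1 - alpha / 2, n, dist[c])
            assert lo <= u.count(c) <= hi, c


@pytest.fixture(scope="module")
def counts():
    return mc.load_codon_usage_counts()


@pytest.fixture(scope="module")
def usages(counts):
    return {sp: CodonUsageTable.from_counts(
                dict(zip(counts["codon"], counts[f"{sp}_count"])))
            for sp in ("bx", "pv")}


class TestPublishedTableConsistency:
    """The packaged per-codon counts table is internally consistent."""

    @pytest.mark.parametrize("species,total", [("bx", 3394), ("pv", 3334)])
    def test_counts_sum_to_codon_total(self, counts, species, total):
        assert counts[f"{species}_count"].sum() == total

    @pytest.mark.parametrize("species", ["bx", "pv"])
    def test_all_64_percentages_recompute(self, counts, species):
        """Every printed percentage equals count/total at two decimals."""
        usage = CodonUsageTable.from_counts(
            dict(zip(counts["codon"], counts[f"{species}_count"])))
        for _, row in counts.iterrows():
            assert usage.percent(row["codon"]) == pytest.approx(row[f"{species}_pct"])

    def test_stop_rows_are_zero(self, counts):
        stops = counts[counts["aa"] == "*"]
        assert (stops[["bx_count", "pv_count"]] == 0).all().all()


class TestTopCodonSummary:
    def test_bx_top3(self, usages):
        codons, pct = mc.top_codon_summary(usages["bx"], 3)
        assert set(codons) == {"TTT", "TTA", "ATT"}
        assert pct == 40.3

    def test_pv_top3(self, usages):
        codons, pct = mc.top_codon_summary(usages["pv"], 3, ndigits=2)
        assert set(codons) == {"TTT", "TTA", "ATT"}
        # unrounded frequencies sum to 31.43; the conventional table value
        # 31.44 arises as the sum of the individually rounded percentages
        assert pct == 31.43
        assert sum(usages["pv"].percent(c) for c in codons) == 31.44

    def test_k64_covers_everything(self, usages):
        _, pct = mc.top_codon_summary(usages["bx"], 64)
        assert pct == 100.0

    def test_k_validated(self, usages):
        with pytest.raises(ValueError):
            mc.top_codon_summary(usages["bx"], 0)
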