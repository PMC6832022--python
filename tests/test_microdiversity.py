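"""Codon pileups, the three SNP validity filters, pN/pS and summaries."""

import random

import pytest

from virodiv.codon import reverse_complement
from virodiv.config import SnpConfig
from virodiv.microdiversity import (
    call_variants,
    category_medians,
    consensus_profile,
    coverage_correlation,
    gene_microdiversity,
    pileup_codons,
)
from virodiv.model import CodonColumn, Gene, GeneMicrodiversity, ReadAlignment


def full_read(read_id, scaffold_id, pos, seq):
    return ReadAlignment(read_id, scaffold_id, [(0, pos, len(seq))], seq)


class TestPileup:
    SCAFFOLD = "AAAA" + "TTTTTTATG" + "CCCC"  # gene at 5..13
    GENE = Gene(id="g1", scaffold_id="s1", start=5, end=13, strand="+")

    def test_reference_reads_no_variants(self):
        reads = [full_read(f"r{i}", "s1", 1, self.SCAFFOLD) for i in range(10)]
        cols = pileup_codons(reads, self.GENE, self.SCAFFOLD)
        assert [c.ref_codon for c in cols] == ["TTT", "TTT", "ATG"]
        assert all(c.coverage == 10 and not c.variant_counts for c in cols)

    def test_read_ending_mid_codon_excluded(self):
        # read covers scaffold 1..9: first two codons fully, third partially
        reads = [full_read("r1", "s1", 1, self.SCAFFOLD[:9])]
        cols = pileup_codons(reads, self.GENE, self.SCAFFOLD)
        assert [c.coverage for c in cols] == [1, 0, 0]

    def test_variant_counted(self):
        mutated = self.SCAFFOLD[:4] + "TTC" + self.SCAFFOLD[7:]
        reads = [full_read("r1", "s1", 1, self.SCAFFOLD),
                 full_read("r2", "s1", 1, mutated)]
        cols = pileup_codons(reads, self.GENE, self.SCAFFOLD)
        assert cols[0].variant_counts == {"TTC": 1}
        assert cols[0].coverage == 2

    def test_n_in_read_codon_ignored(self):
        mutated = self.SCAFFOLD[:4] + "TNT" + self.SCAFFOLD[7:]
        reads = [full_read("r1", "s1", 1, mutated)]
        cols = pileup_codons(reads, self.GENE, self.SCAFFOLD)
        assert cols[0].coverage == 0
        assert cols[0].variant_counts == {}

    def test_indel_inside_codon_excludes_read(self):
        # deletion at ref position 7 splits the read inside codon 0: no
        # single block spans positions 5..7, codons 1 and 2 are intact
        read = ReadAlignment("r1", "s1", [(0, 1, 6), (6, 8, 6)],
                             self.SCAFFOLD[0:6] + self.SCAFFOLD[7:13])
        cols = pileup_codons([read], self.GENE, self.SCAFFOLD)
        assert [c.coverage for c in cols] == [0, 1, 1]

    def test_minus_strand_codon_extraction(self):
        # gene on minus strand: coding = revcomp(scaffold[5..13])
        scaffold = "AAAA" + reverse_complement("TTTTTTATG") + "CCCC"
        gene = Gene(id="g1", scaffold_id="s1", start=5, end=13, strand="-")
        assert gene.coding_sequence(scaffold) == "TTTTTTATG"
        # a read carrying the genomic complement of TTC at codon 0
        # (codon 0 occupies genomic 11..13 for the minus strand)
        variant_genomic = scaffold[:10] + reverse_complement("TTC") + scaffold[13:]
        reads = [full_read("r1", "s1", 1, scaffold),
                 full_read("r2", "s1", 1, variant_genomic)]
        cols = pileup_codons(reads, gene, scaffold)
        assert cols[0].ref_codon == "TTT"
        assert cols[0].variant_counts == {"TTC": 1}


def col(count, coverage, ref="TTT", variant="TTC", gene_id="g1", index=0):
    return CodonColumn(gene_id, index, ref, coverage,
                       {variant: count} if count else {})


class TestFilterBoundaries:
    """The nine pileups around (count 4, frequency 1%, coverage 5)."""

    @pytest.mark.parametrize("count,coverage,valid", [
        (4, 5, True),      # all three at/above their bounds (freq 80%)
        (3, 5, False),     # count below 4
        (4, 4, False),     # coverage below 5 (freq 100%)
        (5, 5, True),      # above everything
        (4, 400, True),    # frequency exactly 1%
        (4, 401, False),   # frequency just under 1%
        (4, 1000, False),  # frequency 0.4%
        (5, 500, True),    # frequency exactly 1% at higher count
        (3, 300, False),   # frequency 1% but count below 4
    ])
    def test_inclusive_thresholds(self, count, coverage, valid):
        (call,) = call_variants([col(count, coverage)])
        assert call.valid is valid

    def test_effect_classification(self):
        syn = call_variants([col(4, 5, ref="TTT", variant="TTC")])[0]
        nonsyn = call_variants([col(4, 5, ref="TTT", variant="TTA")])[0]
        stopgain = call_variants([col(4, 5, ref="TAT", variant="TAA")])[0]
        assert syn.effect == "synonymous"
        assert nonsyn.effect == "nonsynonymous"
        assert stopgain.effect == "nonsynonymous"

    def test_reference_stop_codon_excluded(self):
        assert call_variants([col(4, 5, ref="TAA", variant="TAT")]) == []


class TestGeneMicrodiversity:
    SCAFFOLD = "TTTTTTATG"
    GENE = Gene(id="g1", scaffold_id="s1", start=1, end=9, strand="+")

    def test_worked_pnps_example(self):
        # one valid synonymous (TTT->TTC) and one valid nonsynonymous
        # (ATG->ATA): pnps = (1/1) * ((2/27)/(25/27)) = 0.08
        columns = [
            col(5, 50, ref="TTT", variant="TTC", index=0),
            CodonColumn("g1", 1, "TTT", 50, {}),
            col(5, 50, ref="ATG", variant="ATA", index=2),
        ]
        calls = call_variants(columns)
        gm = gene_microdiversity(calls, columns, self.GENE, self.SCAFFOLD)
        assert gm.obs_n == 1 and gm.obs_s == 1
        assert gm.pnps == pytest.approx(0.08)
        assert gm.p_n == pytest.approx(0.5 / (25 / 27))
        assert gm.p_s == pytest.approx(0.5 / (2 / 27))

    def test_no_variants(self):
        columns = [CodonColumn("g1", i, c, 50, {})
                   for i, c in enumerate(["TTT", "TTT", "ATG"])]
        gm = gene_microdiversity([], columns, self.GENE, self.SCAFFOLD)
        assert gm.obs_n == gm.obs_s == 0
        assert gm.pnps is None
        assert gm.percent_polymorphic == 0.0

    def test_percent_polymorphic_over_assayable(self):
        columns = [col(5, 50, index=0),
                   CodonColumn("g1", 1, "TTT", 50, {}),
                   CodonColumn("g1", 2, "ATG", 2, {})]  # below 5x: not assayable
        calls = call_variants(columns)
        gm = gene_microdiversity(calls, columns, self.GENE, self.SCAFFOLD)
        assert gm.n_assayable == 2
        assert gm.n_polymorphic == 1
        assert gm.percent_polymorphic == pytest.approx(50.0)

    def test_read_weighted_mode(self):
        columns = [col(8, 50, ref="TTT", variant="TTC", index=0),
                   col(4, 50, ref="ATG", variant="ATA", index=2)]
        calls = call_variants(columns)
        gm = gene_microdiversity(calls, columns, self.GENE, self.SCAFFOLD,
                                 SnpConfig(count_mode="reads"))
        assert gm.obs_s == 8 and gm.obs_n == 4

    def test_invariant_to_read_order(self):
        rng = random.Random(9)
        scaffold = "AAAA" + "TTTTTTATG" + "CCCC"
        gene = Gene(id="g1", scaffold_id="s1", start=5, end=13, strand="+")
        mutated = scaffold[:4] + "TTC" + scaffold[7:]
        reads = [full_read(f"r{i}", "s1", 1, scaffold) for i in range(20)]
        reads += [full_read(f"v{i}", "s1", 1, mutated) for i in range(5)]
        shuffled = reads[:]
        rng.shuffle(shuffled)

        def stats(rs):
            cols = pileup_codons(rs, gene, scaffold)
            return gene_microdiversity(call_variants(cols), cols, gene, scaffold)

        assert stats(reads).percent_polymorphic == stats(shuffled).percent_polymorphic


def gm(gene_id, pnps_pair=None, n_poly=1, n_assay=100, coverage=50.0,
       category="replication", sample="15m"):
    obs_n, obs_s = pnps_pair if pnps_pair else (0, 0)
    g = GeneMicrodiversity(
        gene_id=gene_id, category_broad=category, category_specific="x",
        obs_n=obs_n, obs_s=obs_s, f_n=0.75, f_s=0.25,
        n_polymorphic=n_poly, n_assayable=n_assay, mean_coverage=coverage,
        sample_id=sample,
    )
    return g


class TestCategoryMedians:
    def test_group_below_three_genes_omitted(self):
        stats = [gm("g1", (3, 3)), gm("g2", (3, 3))]
        (row,) = category_medians(stats)
        assert row["median_pnps"] is None
        assert row["median_percent_polymorphic"] is not None

    def test_odd_median(self):
        # pnps = (obs_n/obs_s)*(f_s/f_n) with f_s/f_n = 1/3
        stats = [gm("g1", (3, 10)), gm("g2", (9, 10)), gm("g3", (15, 10))]
        (row,) = category_medians(stats)
        assert row["median_pnps"] == pytest.approx((9 / 10) * (1 / 3))

    def test_zero_ps_gene_excluded_from_pnps(self):
        stats = [gm("g1", (3, 0)), gm("g2", (3, 3)), gm("g3", (3, 3)),
                 gm("g4", (3, 3))]
        (row,) = category_medians(stats)
        assert row["n_pnps_genes"] == 3

    def test_low_percent_polymorphic_excluded_from_pnps(self):
        qualifying = [gm(f"g{i}", (3, 3)) for i in range(3)]
        too_low = gm("gx", (30, 30), n_poly=1, n_assay=1000)  # 0.1% < 1%
        (row,) = category_medians(qualifying + [too_low])
        assert row["n_pnps_genes"] == 3

    def test_groups_split_by_category(self):
        stats = [gm(f"g{i}", (3, 3)) for i in range(3)]
        stats += [gm(f"h{i}", (6, 3), category="structural") for i in range(3)]
        rows = category_medians(stats)
        by_cat = {r["category_broad"]: r["median_pnps"] for r in rows}
        assert by_cat["replication"] == pytest.approx(1 / 3)
        assert by_cat["structural"] == pytest.approx(2 / 3)


class TestConsensusProfile:
    def test_reference_majority(self):
        columns = [col(1, 10, ref="TTT", variant="TTA")]
        (row,) = consensus_profile(columns)
        assert row["consensus_aa"] == "F"
        assert row["frequency"] == pytest.approx(0.9)
        assert not row["polymorphic"]  # count 1 < 4

    def test_monomorphic(self):
        (row,) = consensus_profile([CodonColumn("g1", 0, "TTT", 10, {})])
        assert row["frequency"] == 1.0
        assert not row["polymorphic"]

    def test_tie_resolves_to_reference(self):
        columns = [col(5, 10, ref="TTT", variant="TTA")]
        (row,) = consensus_profile(columns)
        assert row["consensus_aa"] == "F"
        assert row["frequency"] == pytest.approx(0.5)
        assert row["polymorphic"]  # count 5 >= 4, freq 50%, cov 10

    def test_synonymous_variant_keeps_consensus_aa(self):
        columns = [col(6, 10, ref="TTT", variant="TTC")]
        (row,) = consensus_profile(columns)
        assert row["consensus_aa"] == "F"
        assert row["frequency"] == 1.0


class TestCoverageCorrelation:
    def test_perfect_linearity(self):
        stats = [gm(f"g{i}", n_poly=i + 1, n_assay=100, coverage=10.0 * (i + 1))
                 for i in range(4)]
        for g, pct in zip(stats, (2, 4, 6, 8)):
            g.n_polymorphic = pct
        r = coverage_correlation(stats, "percent_polymorphic")
        assert r == pytest.approx(1.0)

    def test_constant_metric_undefined(self):
        stats = [gm(f"g{i}", n_poly=5, coverage=10.0 * (i + 1)) for i in range(4)]
        assert coverage_correlation(stats, "percent_polymorphic") is None

    def test_four_point_oracle(self):
        import numpy as np
        xs = [10.0, 20.0, 30.0, 40.0]
        ys = [1.0, 3.0, 2.0, 5.0]
        stats = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            g = gm(f"g{i}", coverage=x, n_assay=100)
            g.n_polymorphic = int(y)
            stats.append(g)
        # brute-force covariance / sigma formula
        mx, my = np.mean(xs), np.mean(ys)
        expected = (sum((a - mx) * (b - my) for a, b in zip(xs, ys)) /
                    (np.sqrt(sum((a - mx) ** 2 for a in xs)) *
                     np.sqrt(sum((b - my) ** 2 for b in ys))))
        assert coverage_correlation(stats, "percent_polymorphic") == \
            pytest.approx(expected)

    def test_too_few_genes(self):
        assert coverage_correlation([gm("g1", (1, 1)), gm("g2", (1, 1))]) is None
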