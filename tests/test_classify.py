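"""Three-round viral identification, concordance, and population clustering."""

import random

import pytest

from virodiv.classify import (
    apply_curation,
    avq_round1,
    bait_round2,
    cluster_populations,
    concordance,
)
from virodiv.model import Classification, Gene, ProteinHit, Scaffold


def make_genes(n, scaffold_id="s1"):
    return [
        Gene(id=f"{scaffold_id}_g{i}", scaffold_id=scaffold_id,
             start=1 + 300 * i, end=300 * (i + 1), strand="+")
        for i in range(n)
    ]


def og_hit(gene_id, og, evalue=1e-10, bitscore=100.0):
    return ProteinHit(gene_id, og, 50.0, 60, bitscore, evalue)


class TestAvqRound1:
    QUOTIENTS = {"VOG1": 1.0, "VOG2": 1.0, "VOG3": 0.5}

    def test_two_hits_of_ten_orfs_pass(self):
        genes = make_genes(10)
        hits = [og_hit(genes[0].id, "VOG1"), og_hit(genes[1].id, "VOG2")]
        res = avq_round1(genes, hits, self.QUOTIENTS)
        assert res.percent_hit == 20.0
        assert res.avq == 2.0
        assert res.passed_round1

    def test_both_boundaries_inclusive(self):
        # exactly 10% of ORFs hit and AVQ exactly 2 still passes
        genes = make_genes(20)
        hits = [og_hit(genes[0].id, "VOG1"), og_hit(genes[1].id, "VOG2")]
        res = avq_round1(genes, hits, self.QUOTIENTS)
        assert res.percent_hit == 10.0
        assert res.avq == 2.0
        assert res.passed_round1

    def test_avq_below_two_fails(self):
        genes = make_genes(10)
        res = avq_round1(genes, [og_hit(genes[0].id, "VOG1")], self.QUOTIENTS)
        assert res.avq == 1.0
        assert not res.passed_round1

    def test_best_hit_is_lowest_evalue(self):
        genes = make_genes(10)
        hits = [
            og_hit(genes[0].id, "VOG3", evalue=1e-20),
            og_hit(genes[0].id, "VOG1", evalue=1e-10),
            og_hit(genes[1].id, "VOG1"), og_hit(genes[2].id, "VOG2"),
        ]
        res = avq_round1(genes, hits, self.QUOTIENTS)
        assert res.avq == pytest.approx(0.5 + 1.0 + 1.0)

    def test_evalue_filter_applied_before_best_hit(self):
        genes = make_genes(10)
        hits = [og_hit(genes[0].id, "VOG1", evalue=1e-3)]
        res = avq_round1(genes, hits, self.QUOTIENTS)
        assert res.n_orfs_with_pvog_hit == 0

    def test_unknown_og_named_in_error(self):
        genes = make_genes(5)
        with pytest.raises(ValueError, match="VOG999"):
            avq_round1(genes, [og_hit(genes[0].id, "VOG999")], self.QUOTIENTS)

    def test_adding_a_hit_never_unpasses(self):
        # monotonicity: extra hits only increase percent and AVQ
        rng = random.Random(5)
        genes = make_genes(10)
        hits = [og_hit(genes[0].id, "VOG1"), og_hit(genes[1].id, "VOG2")]
        assert avq_round1(genes, hits, self.QUOTIENTS).passed_round1
        for i in range(2, 10):
            hits.append(og_hit(genes[i].id, rng.choice(["VOG1", "VOG2", "VOG3"])))
            assert avq_round1(genes, hits, self.QUOTIENTS).passed_round1


class TestBaitRound2:
    ORF_MAP = {f"bait{x}_g{i}": f"bait{x}" for x in "XY" for i in range(20)}

    def hit(self, query, subject, identity=50.0, bitscore=100.0,
            aln=60, evalue=1e-10):
        return ProteinHit(query, subject, identity, aln, bitscore, evalue)

    def test_three_of_ten_orfs_recruit(self):
        genes = make_genes(10, "cand")
        hits = [self.hit(genes[i].id, f"baitX_g{i}") for i in range(3)]
        res = bait_round2(genes, hits, self.ORF_MAP)
        assert res.recruited
        assert res.best_bait_scaffold == "baitX"
        assert res.percent_matched == 30.0

    def test_three_of_twenty_below_percent(self):
        genes = make_genes(20, "cand")
        hits = [self.hit(genes[i].id, f"baitX_g{i}") for i in range(3)]
        assert not bait_round2(genes, hits, self.ORF_MAP).recruited

    def test_hits_split_across_baits_do_not_pool(self):
        # 2 ORFs to X and 2 to Y never reach the per-scaffold minimum of 3
        genes = make_genes(10, "cand")
        hits = [self.hit(genes[0].id, "baitX_g0"), self.hit(genes[1].id, "baitX_g1"),
                self.hit(genes[2].id, "baitY_g0"), self.hit(genes[3].id, "baitY_g1")]
        res = bait_round2(genes, hits, self.ORF_MAP)
        assert not res.recruited
        assert res.n_matched_to_best == 2

    def test_multiple_hits_per_orf_count_once(self):
        genes = make_genes(10, "cand")
        hits = [self.hit(genes[0].id, f"baitX_g{j}") for j in range(5)]
        hits += [self.hit(genes[1].id, "baitX_g0"), self.hit(genes[2].id, "baitX_g1")]
        res = bait_round2(genes, hits, self.ORF_MAP)
        assert res.n_matched_to_best == 3
        assert res.recruited

    @pytest.mark.parametrize("kwargs", [
        {"identity": 29.9}, {"bitscore": 49.9}, {"aln": 29}, {"evalue": 2e-5},
    ])
    def test_each_filter_excludes(self, kwargs):
        genes = make_genes(10, "cand")
        hits = [self.hit(genes[i].id, f"baitX_g{i}") for i in range(2)]
        hits.append(self.hit(genes[2].id, "baitX_g2", **kwargs))
        res = bait_round2(genes, hits, self.ORF_MAP)
        assert res.n_matched_to_best == 2
        assert not res.recruited

    def test_filter_boundaries_inclusive(self):
        genes = make_genes(10, "cand")
        hits = [self.hit(genes[i].id, f"baitX_g{i}", identity=30.0,
                         bitscore=50.0, aln=30, evalue=1e-5) for i in range(3)]
        assert bait_round2(genes, hits, self.ORF_MAP).recruited


class TestCuration:
    def test_unclassified_becomes_curated(self):
        scaffolds = {"s1": Scaffold("s1", "15m", "A" * 5000)}
        apply_curation(scaffolds, ["s1"])
        assert scaffolds["s1"].classification is Classification.viral_curated

    def test_empty_list_no_change(self):
        scaffolds = {"s1": Scaffold("s1", "15m", "A" * 5000)}
        apply_curation(scaffolds, [])
        assert scaffolds["s1"].classification is Classification.unclassified

    def test_already_viral_unchanged_with_warning(self, caplog):
        s = Scaffold("s1", "15m", "A" * 5000)
        s.set_classification(Classification.viral_round1)
        with caplog.at_level("WARNING", logger="virodiv"):
            apply_curation({"s1": s}, ["s1"])
        assert s.classification is Classification.viral_round1
        assert "already classified" in caplog.text

    def test_unknown_id_is_error(self):
        with pytest.raises(ValueError, match="sX"):
            apply_curation({"s1": Scaffold("s1", "15m", "A" * 5000)}, ["sX"])


class TestConcordance:
    @staticmethod
    def label(cat=None, score=None, p=None):
        return {"virsorter_category": cat, "virfinder_score": score,
                "virfinder_p": p}

    def test_published_counts_give_2_3_percent(self):
        ids = [f"s{i}" for i in range(7164)]
        labels = {sid: self.label(cat=1) for sid in ids}
        for sid in ids[:166]:
            labels[sid] = self.label(cat=None, score=0.1, p=0.9)
        n, pct = concordance(ids, labels)
        assert n == 166
        assert pct == 2.3

    def test_all_virsorter_category1_concordant(self):
        ids = ["a", "b", "c"]
        labels = {sid: self.label(cat=1) for sid in ids}
        assert concordance(ids, labels) == (0, 0.0)

    def test_virfinder_boundaries_inclusive(self):
        labels = {"a": self.label(score=0.7, p=0.05)}
        assert concordance(["a"], labels) == (0, 0.0)

    def test_missing_label_counts_discordant(self, caplog):
        with caplog.at_level("WARNING", logger="virodiv"):
            n, pct = concordance(["a", "b"], {"a": self.label(cat=2)})
        assert n == 1 and pct == 50.0


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


class TestClusterPopulations:
    def test_identical_pair_one_population(self):
        rng = random.Random(3)
        seq = "".join(rng.choices("ACGT", k=10000))
        scaffolds = [Scaffold("a", "15m", seq), Scaffold("b", "15m", seq)]
        pops = cluster_populations(scaffolds)
        assert pops["a"] == pops["b"]

    def test_ninety_percent_identity_separate(self):
        # oracle: direct Hamming identity of the mutated copy is 90% < 95%
        rng = random.Random(4)
        seq = "".join(rng.choices("ACGT", k=10000))
        positions = rng.sample(range(10000), 1000)
        mutated = _mutate(seq, positions, rng)
        hamming = sum(1 for x, y in zip(seq, mutated) if x == y) / len(seq)
        assert hamming == pytest.approx(0.9)
        pops = cluster_populations([Scaffold("a", "15m", seq),
                                    Scaffold("b", "15m", mutated)])
        assert pops["a"] != pops["b"]

    def test_near_identical_pair_links(self):
        rng = random.Random(5)
        seq = "".join(rng.choices("ACGT", k=10000))
        mutated = _mutate(seq, rng.sample(range(10000), 100), rng)  # 99% ANI
        pops = cluster_populations([Scaffold("a", "15m", seq),
                                    Scaffold("b", "15m", mutated)])
        assert pops["a"] == pops["b"]

    def test_all_singletons(self):
        rng = random.Random(6)
        scaffolds = [
            Scaffold(f"s{i}", "15m", "".join(rng.choices("ACGT", k=8000)))
            for i in range(4)
        ]
        pops = cluster_populations(scaffolds)
        assert len(set(pops.values())) == 4

    def test_order_invariant(self):
        rng = random.Random(7)
        seq = "".join(rng.choices("ACGT", k=9000))
        scaffolds = [
            Scaffold("a", "15m", seq),
            Scaffold("b", "15m", _mutate(seq, rng.sample(range(9000), 90), rng)),
            Scaffold("c", "15m", "".join(rng.choices("ACGT", k=9000))),
        ]
        forward = cluster_populations(list(scaffolds))
        backward = cluster_populations(list(reversed(scaffolds)))
        assert forward == backward

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            cluster_populations([Scaffold("a", "15m", "A" * 6000),
                                 Scaffold("b", "45m", "A" * 6000)])
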