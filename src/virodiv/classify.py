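"""Three-round identification of bona fide viral scaffolds.

Round 1 screens each scaffold by the share of its ORFs with hits to a
pVOG-like orthologous-group database and by the added viral quotient (AVQ):
the sum, over ORFs, of the viral quotient of each ORF's best hit. Round 2
"baits" further scaffolds whose proteins match the round-1 viral protein set.
Round 3 applies a manually curated id list. Concordance against external
classifier labels and ANI-based viral-population clustering live here too.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict

from .config import BaitConfig, ClassifierLabelConfig, PopulationConfig
from .model import AvqResult, BaitResult, Classification, Gene, ProteinHit, Scaffold

logger = logging.getLogger("virodiv")


def _best_hit(hits: list[ProteinHit]) -> ProteinHit:
    """Lowest E value; ties by highest bitscore, then lexicographic subject."""
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def avq_round1(
    genes: list[Gene],
    hits: list[ProteinHit],
    quotients: dict[str, float],
    min_percent: float = 10.0,
    min_avq: float = 2.0,
    max_evalue: float = 1e-5,
) -> AvqResult:
    """Round-1 AVQ screen for one scaffold.

    Both thresholds are inclusive: a scaffold passes with exactly 10% of its
    ORFs hit and an AVQ of exactly 2.
    """
    if not genes:
        raise ValueError("avq_round1 requires at least one ORF")
    scaffold_id = genes[0].scaffold_id
    gene_ids = {g.id for g in genes}
    by_gene: dict[str, list[ProteinHit]] = defaultdict(list)
    for h in hits:
        if h.query_gene_id in gene_ids and h.evalue <= max_evalue:
            by_gene[h.query_gene_id].append(h)
    avq = 0.0
    for gid, gene_hits in by_gene.items():
        best = _best_hit(gene_hits)
        if best.subject_id not in quotients:
            raise ValueError(
                f"gene {gid}: best hit to unknown orthologous group {best.subject_id}"
            )
        avq += quotients[best.subject_id]
    n_hit = len(by_gene)
    percent = 100.0 * n_hit / len(genes)
    return AvqResult(
        scaffold_id=scaffold_id,
        n_orfs=len(genes),
        n_orfs_with_pvog_hit=n_hit,
        avq=avq,
        passed_round1=percent >= min_percent and avq >= min_avq,
    )


def bait_round2(
    candidate_genes: list[Gene],
    hits: list[ProteinHit],
    orf_to_scaffold: dict[str, str],
    config: BaitConfig | None = None,
) -> BaitResult:
    """Round-2 protein baiting for one unclassified candidate scaffold.

    ``hits`` are the candidate's ORFs queried against round-1 viral ORFs;
    ``orf_to_scaffold`` resolves subject ORF ids to their round-1 scaffold.
    The match count is evaluated per bait scaffold (distinct candidate ORFs
    with at least one passing hit to that single scaffold), never pooled.
    """
    cfg = config or BaitConfig()
    if not candidate_genes:
        raise ValueError("bait_round2 requires at least one ORF")
    candidate_id = candidate_genes[0].scaffold_id
    gene_ids = {g.id for g in candidate_genes}

    passing = [
        h for h in hits
        if h.query_gene_id in gene_ids
        and h.percent_identity >= cfg.min_identity
        and h.bitscore >= cfg.min_bitscore
        and h.aln_length_aa >= cfg.min_aln_len
        and h.evalue <= cfg.max_evalue
    ]
    if cfg.best_hit_only:
        by_gene: dict[str, list[ProteinHit]] = defaultdict(list)
        for h in passing:
            by_gene[h.query_gene_id].append(h)
        passing = [_best_hit(hs) for hs in by_gene.values()]

    orfs_per_bait: dict[str, set[str]] = defaultdict(set)
    bitscore_per_bait: dict[str, float] = defaultdict(float)
    for h in passing:
        bait = orf_to_scaffold.get(h.subject_id)
        if bait is None:
            raise ValueError(f"hit subject {h.subject_id} is not a round-1 ORF")
        orfs_per_bait[bait].add(h.query_gene_id)
        bitscore_per_bait[bait] += h.bitscore

    if not orfs_per_bait:
        return BaitResult(candidate_id, len(candidate_genes), None, 0, False)
    best = max(
        orfs_per_bait,
        key=lambda s: (len(orfs_per_bait[s]), bitscore_per_bait[s], s),
    )
    n = len(orfs_per_bait[best])
    recruited = n >= cfg.min_matches and 100.0 * n / len(candidate_genes) >= cfg.min_percent
    return BaitResult(
        scaffold_id=candidate_id,
        n_orfs=len(candidate_genes),
        best_bait_scaffold=best if recruited else None,
        n_matched_to_best=n,
        recruited=recruited,
    )


def apply_curation(scaffolds: dict[str, Scaffold], curated_ids: list[str]) -> None:
    """Mark listed unclassified scaffolds as manually curated viral."""
    for sid in curated_ids:
        if sid not in scaffolds:
            raise ValueError(f"curated id {sid} not among scaffolds")
        scaf = scaffolds[sid]
        if scaf.classification.is_viral:
            logger.warning("curated id %s already classified %s; unchanged",
                           sid, scaf.classification.value)
            continue
        scaf.set_classification(Classification.viral_curated)


def concordance(
    bona_fide_ids: list[str],
    labels: dict[str, dict],
    config: ClassifierLabelConfig | None = None,
) -> tuple[int, float]:
    """Share of bona fide viral scaffolds flagged by NEITHER external tool.

    A scaffold is concordant if VirSorter placed it in an accepted category
    or VirFinder gave it score >= 0.7 with P <= 0.05 (boundaries inclusive).
    Returns (n_discordant, percent rounded to one decimal).
    """
    cfg = config or ClassifierLabelConfig()
    n_discordant = 0
    for sid in bona_fide_ids:
        row = labels.get(sid)
        if row is None:
            logger.warning("no external label for %s; counted discordant", sid)
            n_discordant += 1
            continue
        by_vs = row.get("virsorter_category") in cfg.virsorter_categories
        score, pval = row.get("virfinder_score"), row.get("virfinder_p")
        by_vf = (
            score is not None and pval is not None
            and score >= cfg.virfinder_min_score and pval <= cfg.virfinder_max_p
        )
        if not (by_vs or by_vf):
            n_discordant += 1
    percent = round(100.0 * n_discordant / len(bona_fide_ids), 1)
    return n_discordant, percent


# ---------------------------------------------------------------------------
# Viral-population clustering

def _diagonal_identity(a: str, b: str, k: int) -> tuple[float, float]:
    """(percent identity, percent of shorter sequence covered) on the best
    shared-k-mer diagonal, by ungapped comparison over the diagonal overlap."""
    if len(a) < k or len(b) < k:
        return 0.0, 0.0
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(a) - k + 1):
        index[a[i : i + k]].append(i)
    diagonals: Counter[int] = Counter()
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            diagonals[i - j] += 1
    if not diagonals:
        return 0.0, 0.0
    diag = max(diagonals, key=lambda d: (diagonals[d], -abs(d)))
    # overlap of a[i] vs b[i - diag]
    start = max(0, diag)
    end = min(len(a), len(b) + diag)
    if end <= start:
        return 0.0, 0.0
    matches = sum(
        1 for i in range(start, end)
        if a[i] == b[i - diag] and a[i] != "N"
    )
    overlap = end - start
    identity = 100.0 * matches / overlap
    coverage = 100.0 * overlap / min(len(a), len(b))
    return identity, coverage


def cluster_populations(
    scaffolds: list[Scaffold],
    config: PopulationConfig | None = None,
) -> dict[str, str]:
    """Cluster one sample's scaffolds into viral populations.

    Two scaffolds are linked when their estimated nucleotide identity is at
    least ``ani`` over at least ``cov`` percent of the shorter sequence;
    populations are the connected components (singletons allowed). The
    result maps scaffold id -> population id and is invariant to input order.
    """
    cfg = config or PopulationConfig()
    samples = {s.sample_id for s in scaffolds}
    if len(samples) > 1:
        raise ValueError(f"cluster_populations is per-sample; got {sorted(samples)}")
    ordered = sorted(scaffolds, key=lambda s: s.id)
    parent = {s.id: s.id for s in ordered}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            ident, cov = _diagonal_identity(a.sequence, b.sequence, cfg.kmer)
            if ident >= cfg.ani and cov >= cfg.cov:
                parent[find(b.id)] = find(a.id)

    roots = sorted({find(s.id) for s in ordered})
    pop_names = {root: f"pop_{n + 1:04d}" for n, root in enumerate(roots)}
    assignment = {s.id: pop_names[find(s.id)] for s in ordered}
    for s in scaffolds:
        s.population_id = assignment[s.id]
    return assignment


# ---------------------------------------------------------------------------
# Orchestration over a whole community

def classify_community(
    scaffolds: dict[str, Scaffold],
    genes_by_scaffold: dict[str, list[Gene]],
    pvog_hits: list[ProteinHit],
    quotients: dict[str, float],
    bait_hits: list[ProteinHit] | None = None,
    curated_ids: list[str] | None = None,
    avq_kwargs: dict | None = None,
    bait_config: BaitConfig | None = None,
) -> tuple[dict[str, AvqResult], dict[str, BaitResult]]:
    """Run the three identification rounds over a community in place.

    Round 2 consumes only round-1 positives as bait, in a single pass; a
    scaffold recruited in round 2 is never itself reused as bait.
    """
    hits_by_scaffold: dict[str, list[ProteinHit]] = defaultdict(list)
    gene_owner = {
        g.id: sid for sid, genes in genes_by_scaffold.items() for g in genes
    }
    for h in pvog_hits:
        owner = gene_owner.get(h.query_gene_id)
        if owner is not None:
            hits_by_scaffold[owner].append(h)

    avq_results: dict[str, AvqResult] = {}
    for sid in sorted(scaffolds):
        genes = genes_by_scaffold.get(sid, [])
        if not genes:
            continue
        res = avq_round1(genes, hits_by_scaffold.get(sid, []), quotients,
                         **(avq_kwargs or {}))
        avq_results[sid] = res
        if res.passed_round1:
            scaffolds[sid].set_classification(Classification.viral_round1)

    orf_to_scaffold = {
        g.id: sid
        for sid, genes in genes_by_scaffold.items()
        if scaffolds[sid].classification is Classification.viral_round1
        for g in genes
    }
    bait_results: dict[str, BaitResult] = {}
    if bait_hits:
        for sid in sorted(scaffolds):
            if scaffolds[sid].classification is not Classification.unclassified:
                continue
            genes = genes_by_scaffold.get(sid, [])
            if not genes:
                continue
            res = bait_round2(genes, bait_hits, orf_to_scaffold, bait_config)
            bait_results[sid] = res
            if res.recruited:
                scaffolds[sid].set_classification(Classification.viral_round2)

    if curated_ids:
        apply_curation(scaffolds, curated_ids)
    for scaf in scaffolds.values():
        if scaf.classification is Classification.unclassified:
            scaf.set_classification(Classification.nonviral)
    return avq_results, bait_results
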