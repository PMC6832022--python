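"""Synthetic communities with known ground truth.

Generates scaffolds, ORFs, pVOG-like hit tables, taxonomy reference hits,
host-signal fixtures and SAM reads carrying codon variants at controlled
frequencies, coverages and selection strength, plus machine-readable truth
tables, so every downstream stage is testable without external downloads.

The selection model: proposed variants are drawn uniformly from a codon's 9
single-nucleotide neighbours; synonymous proposals are always accepted,
nonsynonymous ones with probability ``alpha``. A rejected proposal redraws
both the site and the neighbour, so the expected planted
nonsynonymous:synonymous ratio is alpha times the gene's neutral opportunity
ratio and the expected pN/pS equals alpha exactly — alpha = 1 is neutrality,
alpha < 1 purifying selection.
"""

from __future__ import annotations

import hashlib
import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .codon import (
    CODON_TO_AA,
    all_sense_codons,
    reverse_complement,
    single_nucleotide_neighbors,
    translate_codon,
)
from .io import write_fasta, write_gff3, write_hits_table, write_sam
from .model import Gene, ProteinHit, Scaffold

logger = logging.getLogger("virodiv")

READ_LENGTH_DEFAULT = 150  # matches short-read virome sequencing
_GENE_MARGIN = 200  # bp kept gene-free at scaffold ends (>= read length)
_STOPS = ("TAA", "TAG", "TGA")

_PRODUCTS = {
    "replication": ["DNA polymerase", "DNA primase", "helicase",
                    "ribonucleotide reductase"],
    "structural": ["major capsid protein", "tail fiber protein",
                   "portal protein", "terminase large subunit"],
    "metabolism": ["thioredoxin", "2OG-Fe(II) oxygenase",
                   "phosphate starvation-inducible protein"],
    "regulation": ["transcriptional regulator"],
    "unknown": ["hypothetical protein"],
}

_DEFAULT_HOSTS = (
    ("host_pelagibacter", {"phylum": "Proteobacteria", "genus": "Pelagibacter"}),
    ("host_prochlorococcus", {"phylum": "Cyanobacteria", "genus": "Prochlorococcus"}),
    ("host_sar86", {"phylum": "Proteobacteria", "genus": "SAR86"}),
)


def _stream(seed: int, *labels: str) -> random.Random:
    """Independent RNG stream derived by stable hashing, so adding a
    scaffold never perturbs the others."""
    key = ":".join((str(seed),) + labels).encode()
    return random.Random(int.from_bytes(
        hashlib.blake2b(key, digest_size=8).digest(), "big"
    ))


@dataclass
class CommunityConfig:
    """Shape of a synthetic community.

    ``n_viral`` scaffolds are constructed to pass the round-1 AVQ screen
    (>= 3 pVOG hits at quotients >= the viral quotient range floor);
    ``n_viral_round2`` are viral scaffolds recruitable only by round-2
    baiting; ``n_nonviral`` receive too few/too weak hits to pass anything.
    """

    n_viral: int = 10
    n_viral_round2: int = 4
    n_nonviral: int = 10
    scaffold_length: tuple[int, int] = (8000, 12000)
    genes_per_scaffold: tuple[int, int] = (8, 12)
    gene_length_aa: tuple[int, int] = (80, 250)
    pvog_hit_fraction_viral: float = 0.3
    pvog_hit_fraction_nonviral: float = 0.1
    quotient_range_viral: tuple[float, float] = (0.7, 1.0)
    quotient_range_nonviral: tuple[float, float] = (0.0, 0.3)
    category_proportions: dict[str, float] = field(default_factory=lambda: {
        "replication": 0.20, "structural": 0.30, "metabolism": 0.15,
        "regulation": 0.10, "unknown": 0.25,
    })
    families: tuple[str, ...] = ("Myoviridae", "Podoviridae", "Siphoviridae")
    hosts: tuple = _DEFAULT_HOSTS
    host_fraction: float = 0.5
    n_ambiguous_hosts: int = 0
    sample_id: str = "15m"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_viral, self.n_viral_round2, self.n_nonviral) < 0:
            raise ValueError("scaffold counts must be >= 0")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")


@dataclass
class MicrodivSpec:
    """Read-simulation parameters for one gene.

    ``coverage`` is the mean number of reads fully spanning each codon;
    ``alpha`` in (0, 1] is the acceptance probability of a proposed
    nonsynonymous variant (synonymous proposals are always accepted).
    """

    coverage: float = 50.0
    n_variant_sites: int = 100
    freq_range: tuple[float, float] = (0.05, 0.5)
    alpha: float = 1.0
    read_length: int = READ_LENGTH_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        lo, hi = self.freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("frequencies must be in (0, 1)")


@dataclass
class PlantedVariant:
    gene_id: str
    codon_index: int
    ref_codon: str
    variant_codon: str
    frequency: float
    effect: str
    alpha: float


@dataclass
class ScaffoldTruth:
    scaffold_id: str
    planted_class: str  # viral_round1 | viral_round2 | nonviral
    family: str | None = None
    genus: str | None = None
    species: str | None = None
    hosts: list[tuple[str, dict[str, str]]] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    scaffolds: dict[str, ScaffoldTruth] = field(default_factory=dict)
    variants: dict[str, list[PlantedVariant]] = field(default_factory=dict)


@dataclass
class CommunityBundle:
    """In-memory view of an emitted community plus its truth."""

    scaffolds: dict[str, Scaffold]
    genes_by_scaffold: dict[str, list[Gene]]
    pvog_hits: list[ProteinHit]
    quotients: dict[str, float]
    bait_hits: list[ProteinHit]
    ref_hits: list[ProteinHit]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Community generation

def _make_gene(rng: random.Random, gene_id: str, scaffold_id: str, start: int,
               length_aa: int, category: str) -> tuple[Gene, str]:
    """A stop-free coding sequence of ``length_aa`` residues plus stop."""
    sense = [c for c in all_sense_codons() if c != "ATG"]
    codons = ["ATG"] + [rng.choice(sense) for _ in range(length_aa - 1)]
    codons.append(rng.choice(_STOPS))
    coding = "".join(codons)
    strand = rng.choice("+-")
    gene = Gene(
        id=gene_id,
        scaffold_id=scaffold_id,
        start=start,
        end=start + len(coding) - 1,
        strand=strand,
    )
    protein = "".join(CODON_TO_AA[c] for c in codons[:-1])
    gene.protein = protein
    gene.category_broad = category
    gene.category_specific = rng.choice(_PRODUCTS[category])
    return gene, coding


def _build_scaffold(cfg: CommunityConfig, scaffold_id: str
                    ) -> tuple[Scaffold, list[Gene]]:
    rng = _stream(cfg.seed, "scaffold", scaffold_id)
    length = rng.randint(*cfg.scaffold_length)
    n_genes = rng.randint(*cfg.genes_per_scaffold)
    min_gene_bp = 3 * cfg.gene_length_aa[0] + 3
    min_gap = 20

    sequence = list(rng.choices("ACGT", k=length))
    categories = list(cfg.category_proportions)
    weights = [cfg.category_proportions[c] for c in categories]
    genes: list[Gene] = []
    pos = _GENE_MARGIN + 1
    for i in range(n_genes):
        reserve = (n_genes - i - 1) * (min_gene_bp + min_gap)
        room = length - _GENE_MARGIN - reserve - pos + 1
        if room < min_gene_bp:
            raise ValueError(
                f"{scaffold_id}: {n_genes} genes do not fit in {length} bp"
            )
        aa_cap = min(cfg.gene_length_aa[1], (room - 3) // 3)
        length_aa = rng.randint(cfg.gene_length_aa[0], aa_cap)
        category = rng.choices(categories, weights=weights)[0]
        gene, coding = _make_gene(rng, f"{scaffold_id}_g{i + 1:02d}",
                                  scaffold_id, pos, length_aa, category)
        inserted = coding if gene.strand == "+" else reverse_complement(coding)
        sequence[gene.start - 1 : gene.end] = list(inserted)
        genes.append(gene)
        pos = gene.end + 1 + rng.randint(min_gap, 80)
    scaffold = Scaffold(id=scaffold_id, sample_id=cfg.sample_id,
                        sequence="".join(sequence))
    return scaffold, genes


def _hit_row(rng: random.Random, gene_id: str, subject: str, kind: str,
             identity_range: tuple[float, float] = (30.0, 90.0),
             taxonomy: dict[str, str] | None = None) -> ProteinHit:
    hit = ProteinHit(
        query_gene_id=gene_id,
        subject_id=subject,
        percent_identity=round(rng.uniform(*identity_range), 1),
        aln_length_aa=rng.randint(40, 200),
        bitscore=round(rng.uniform(60.0, 300.0), 1),
        evalue=10.0 ** -rng.randint(6, 30),
        subject_kind=kind,
    )
    hit.subject_taxonomy = taxonomy
    return hit


def generate_community(cfg: CommunityConfig, outdir: str | Path | None = None
                       ) -> CommunityBundle:
    """Generate a full synthetic community; optionally emit it to disk.

    Deterministic given ``cfg.seed`` (byte-identical files across runs).
    Emits scaffolds.fasta, genes.gff3, proteins.faa, pvog_hits.tsv,
    quotients.tsv, bait_hits.tsv, ref_hits.tsv and truth_scaffolds.tsv.
    """
    rng = _stream(cfg.seed, "community")
    quotients: dict[str, float] = {}
    for i in range(30):
        quotients[f"VOG{i + 1:04d}"] = round(rng.uniform(*cfg.quotient_range_viral), 3)
    for i in range(30, 50):
        quotients[f"VOG{i + 1:04d}"] = round(rng.uniform(*cfg.quotient_range_nonviral), 3)
    viral_ogs = sorted(quotients)[:30]
    weak_ogs = sorted(quotients)[30:]

    truth = SyntheticTruth()
    scaffolds: dict[str, Scaffold] = {}
    genes_by_scaffold: dict[str, list[Gene]] = {}
    pvog_hits: list[ProteinHit] = []
    ref_hits: list[ProteinHit] = []

    def add(sid: str, planted: str) -> list[Gene]:
        scaffold, genes = _build_scaffold(cfg, sid)
        scaffolds[sid] = scaffold
        genes_by_scaffold[sid] = genes
        truth.scaffolds[sid] = ScaffoldTruth(sid, planted)
        return genes

    viral_ids = [f"vir_r1_{i + 1:03d}" for i in range(cfg.n_viral)]
    round2_ids = [f"vir_r2_{i + 1:03d}" for i in range(cfg.n_viral_round2)]
    nonviral_ids = [f"nonvir_{i + 1:03d}" for i in range(cfg.n_nonviral)]

    for sid in viral_ids:
        genes = add(sid, "viral_round1")
        srng = _stream(cfg.seed, "pvog", sid)
        n_hits = max(3, math.ceil(cfg.pvog_hit_fraction_viral * len(genes)))
        for g in sorted(srng.sample(genes, min(n_hits, len(genes))), key=lambda g: g.id):
            og = srng.choice(viral_ogs)
            g.pvog_hit = (og, quotients[og])
            pvog_hits.append(_hit_row(srng, g.id, og, "og"))
    for sid in round2_ids:
        add(sid, "viral_round2")
    for sid in nonviral_ids:
        genes = add(sid, "nonviral")
        srng = _stream(cfg.seed, "pvog", sid)
        n_hits = round(cfg.pvog_hit_fraction_nonviral * len(genes))
        for g in sorted(srng.sample(genes, min(n_hits, len(genes))), key=lambda g: g.id):
            og = srng.choice(weak_ogs)
            g.pvog_hit = (og, quotients[og])
            pvog_hits.append(_hit_row(srng, g.id, og, "og"))

    # round-2 bait hits: each planted recruit matches a single round-1 scaffold
    bait_hits: list[ProteinHit] = []
    for sid in round2_ids:
        srng = _stream(cfg.seed, "bait", sid)
        genes = genes_by_scaffold[sid]
        bait = srng.choice(viral_ids) if viral_ids else None
        if bait is None:
            continue
        m = max(3, math.ceil(0.2 * len(genes)))
        bait_orfs = genes_by_scaffold[bait]
        for g in sorted(srng.sample(genes, min(m, len(genes))), key=lambda g: g.id):
            subject = srng.choice(bait_orfs)
            bait_hits.append(_hit_row(srng, g.id, subject.id, "viral_scaffold_orf",
                                      identity_range=(40.0, 70.0)))
    for sid in nonviral_ids:  # stray sub-threshold matches exercise counting
        srng = _stream(cfg.seed, "bait", sid)
        if viral_ids and srng.random() < 0.5:
            g = srng.choice(genes_by_scaffold[sid])
            subject = srng.choice(genes_by_scaffold[srng.choice(viral_ids)])
            bait_hits.append(_hit_row(srng, g.id, subject.id, "viral_scaffold_orf",
                                      identity_range=(40.0, 70.0)))

    # planted taxonomy + reference hits (majority of ORFs match the taxon)
    for idx, sid in enumerate(viral_ids + round2_ids):
        srng = _stream(cfg.seed, "taxonomy", sid)
        family = cfg.families[idx % len(cfg.families)]
        genus = f"{family[:-4]}virus_{idx % 2 + 1}"
        species = f"{genus}_sp{idx + 1}"
        st = truth.scaffolds[sid]
        st.family, st.genus, st.species = family, genus, species
        genes = genes_by_scaffold[sid]
        n_major = max(2, math.ceil(0.6 * len(genes)))
        shuffled = sorted(genes, key=lambda g: srng.random())
        for g in shuffled[:n_major]:
            ref_hits.append(_hit_row(
                srng, g.id, f"ref_{family}_{srng.randint(1, 5)}",
                "reference_protein", (35.0, 90.0),
                {"family": family, "genus": genus, "species": species},
            ))
        other = cfg.families[(idx + 1) % len(cfg.families)]
        for g in shuffled[n_major : n_major + max(0, len(genes) // 5)]:
            ref_hits.append(_hit_row(
                srng, g.id, f"ref_{other}_{srng.randint(1, 5)}",
                "reference_protein", (30.0, 60.0),
                {"family": other, "genus": f"{other[:-4]}virus_9",
                 "species": f"{other[:-4]}virus_9_spX"},
            ))

    # planted hosts
    host_rng = _stream(cfg.seed, "hosts")
    n_hosted = round(cfg.host_fraction * len(viral_ids))
    hosted = sorted(host_rng.sample(viral_ids, min(n_hosted, len(viral_ids))))
    for i, sid in enumerate(hosted):
        host_id, taxonomy = cfg.hosts[i % len(cfg.hosts)]
        truth.scaffolds[sid].hosts.append((host_id, dict(taxonomy)))
    for sid in hosted[: cfg.n_ambiguous_hosts]:
        first = truth.scaffolds[sid].hosts[0][0]
        alt = next((h, dict(t)) for h, t in cfg.hosts if h != first)
        truth.scaffolds[sid].hosts.append(alt)

    bundle = CommunityBundle(scaffolds, genes_by_scaffold, pvog_hits,
                             quotients, bait_hits, ref_hits, truth)
    if outdir is not None:
        _emit_community(bundle, Path(outdir))
    return bundle


def _emit_community(bundle: CommunityBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(bundle.scaffolds)
    write_fasta([(sid, bundle.scaffolds[sid].sequence) for sid in ordered],
                outdir / "scaffolds.fasta")
    genes = [g for sid in ordered for g in bundle.genes_by_scaffold[sid]]
    write_gff3(genes, outdir / "genes.gff3")
    with open(outdir / "proteins.faa", "w") as fh:
        for g in genes:
            fh.write(f">{g.id}\n{g.protein}\n")
    write_hits_table(sorted(bundle.pvog_hits, key=lambda h: (h.query_gene_id, h.subject_id)),
                     outdir / "pvog_hits.tsv")
    write_hits_table(sorted(bundle.bait_hits, key=lambda h: (h.query_gene_id, h.subject_id)),
                     outdir / "bait_hits.tsv")
    write_hits_table(sorted(bundle.ref_hits, key=lambda h: (h.query_gene_id, h.subject_id)),
                     outdir / "ref_hits.tsv")
    with open(outdir / "quotients.tsv", "w") as fh:
        for og in sorted(bundle.quotients):
            fh.write(f"{og}\t{bundle.quotients[og]}\n")
    with open(outdir / "truth_scaffolds.tsv", "w") as fh:
        fh.write("scaffold_id\tplanted_class\tfamily\tgenus\tspecies\thosts\thost_phyla\n")
        for sid in ordered:
            st = bundle.truth.scaffolds[sid]
            hosts = ",".join(h for h, _ in st.hosts) or "."
            phyla = ",".join(t.get("phylum", ".") for _, t in st.hosts) or "."
            fh.write(f"{sid}\t{st.planted_class}\t{st.family or '.'}\t"
                     f"{st.genus or '.'}\t{st.species or '.'}\t{hosts}\t{phyla}\n")


# ---------------------------------------------------------------------------
# Read simulation with planted codon variants

def plant_variants(gene: Gene, scaffold_sequence: str, spec: MicrodivSpec
                   ) -> list[PlantedVariant]:
    """Plant codon variants under the acceptance-probability selection model.

    Sites are distinct codons (the terminal stop codon is excluded); each
    gets one variant codon drawn from the 9 single-nucleotide neighbours and
    a minor-allele frequency drawn from ``spec.freq_range``.
    """
    rng = _stream(spec.seed, "variants", gene.id)
    coding = gene.coding_sequence(scaffold_sequence)
    n_codons = len(coding) // 3
    plantable = n_codons - 1  # exclude terminal stop codon
    if spec.n_variant_sites > plantable:
        raise ValueError(
            f"{gene.id}: cannot plant {spec.n_variant_sites} sites in "
            f"{plantable} codons"
        )
    planted: dict[int, PlantedVariant] = {}
    attempts = 0
    while len(planted) < spec.n_variant_sites:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError(f"{gene.id}: variant planting did not converge")
        ci = rng.randrange(plantable)
        if ci in planted:
            continue
        ref = coding[3 * ci : 3 * ci + 3]
        variant = rng.choice(single_nucleotide_neighbors(ref))
        synonymous = translate_codon(variant) == translate_codon(ref)
        if not synonymous and rng.random() >= spec.alpha:
            continue  # rejected: redraw site and neighbour
        planted[ci] = PlantedVariant(
            gene_id=gene.id,
            codon_index=ci,
            ref_codon=ref,
            variant_codon=variant,
            frequency=rng.uniform(*spec.freq_range),
            effect="synonymous" if synonymous else "nonsynonymous",
            alpha=spec.alpha,
        )
    return [planted[ci] for ci in sorted(planted)]


def simulate_reads(gene: Gene, scaffold_sequence: str, spec: MicrodivSpec,
                   variants: list[PlantedVariant] | None = None
                   ) -> tuple[list[tuple[str, str, int, str]], list[PlantedVariant]]:
    """Tile a gene with fixed-length reads carrying the planted variants.

    Read starts are uniform over the window of positions overlapping the
    gene; each read spanning a planted codon carries the variant codon with
    the planted frequency (independent Bernoulli per read). Returns
    (reads as (name, scaffold_id, pos_1based, sequence), truth variants);
    planted sites never spanned by a read are dropped from the truth with a
    warning.
    """
    if variants is None:
        variants = plant_variants(gene, scaffold_sequence, spec)
    rng = _stream(spec.seed, "reads", gene.id)
    L = spec.read_length
    win_lo = max(1, gene.start - (L - 3))
    win_hi = min(len(scaffold_sequence) - L + 1, gene.end - 2)
    if win_hi < win_lo:
        raise ValueError(f"{gene.id}: read length {L} exceeds scaffold span")
    window = win_hi - win_lo + 1
    n_reads = max(1, round(spec.coverage * window / (L - 2)))

    site_positions = {
        v.codon_index: _genomic_triple(gene, v.codon_index) for v in variants
    }
    spanned: dict[int, int] = {v.codon_index: 0 for v in variants}
    reads = []
    for r in range(n_reads):
        start = rng.randint(win_lo, win_hi)
        seq = list(scaffold_sequence[start - 1 : start + L - 1])
        for v in variants:
            lo, _mid, hi = site_positions[v.codon_index]
            if start <= lo and hi <= start + L - 1:
                spanned[v.codon_index] += 1
                if rng.random() < v.frequency:
                    genomic = (v.variant_codon if gene.strand == "+"
                               else reverse_complement(v.variant_codon))
                    for k in range(3):
                        seq[lo - start + k] = genomic[k]
        reads.append((f"{gene.id}_r{r + 1:06d}", gene.scaffold_id, start, "".join(seq)))

    kept = []
    for v in variants:
        if spanned[v.codon_index] == 0:
            logger.warning("%s codon %d: no spanning read; site dropped from truth",
                           gene.id, v.codon_index)
        else:
            kept.append(v)
    return reads, kept


def _genomic_triple(gene: Gene, codon_index: int) -> tuple[int, int, int]:
    if gene.strand == "+":
        p = gene.start + 3 * codon_index
        return p, p + 1, p + 2
    p = gene.end - 3 * codon_index
    return p - 2, p - 1, p


def write_reads_sam(reads: list[tuple[str, str, int, str]],
                    scaffolds: dict[str, Scaffold], path: str | Path) -> None:
    refs = [(sid, scaffolds[sid].length) for sid in sorted(scaffolds)]
    write_sam(reads, refs, path)


# ---------------------------------------------------------------------------
# Host fixtures

def emit_host_fixtures(truth: SyntheticTruth, scaffolds: dict[str, Scaffold],
                       outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit CRISPR spacer, shared-tRNA and host-genome homology fixtures.

    For each planted virus-host pair one signal type (cycling crispr ->
    trna -> homology) is embedded verbatim: a 32-bp spacer copied from the
    viral scaffold, an identical 72-nt tRNA in both tRNA files, or a 1.5-kb
    viral segment copied into the host genome. Host taxonomy ships in
    hosts.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacers: list[tuple[str, str]] = []
    viral_trnas: list[tuple[str, str]] = []
    host_trnas: list[tuple[str, str]] = []
    host_genomes: dict[str, list[str]] = {}
    segments: list[tuple[str, str, int, int, int]] = []
    hosts_seen: dict[str, dict[str, str]] = {}
    signal_types = ("crispr", "trna", "homology")

    pair_no = 0
    for sid in sorted(truth.scaffolds):
        st = truth.scaffolds[sid]
        for host_id, taxonomy in st.hosts:
            rng = _stream(seed, "fixture", sid, host_id)
            hosts_seen[host_id] = taxonomy
            signal = signal_types[pair_no % len(signal_types)]
            pair_no += 1
            scaffold = scaffolds[sid]
            if host_id not in host_genomes:
                grng = _stream(seed, "hostgenome", host_id)
                host_genomes[host_id] = list(grng.choices("ACGT", k=15000))
            if signal == "crispr":
                pos = rng.randint(0, scaffold.length - 32)
                spacers.append((f"sp_{pair_no:03d}|host={host_id}",
                                scaffold.sequence[pos : pos + 32]))
            elif signal == "trna":
                trna = "".join(rng.choices("ACGT", k=72))
                viral_trnas.append((f"trna_v_{pair_no:03d}|scaffold={sid}", trna))
                host_trnas.append((f"trna_h_{pair_no:03d}|host={host_id}", trna))
            else:
                seg_len = 1500
                vpos = rng.randint(0, scaffold.length - seg_len)
                hpos = rng.randint(0, len(host_genomes[host_id]) - seg_len)
                host_genomes[host_id][hpos : hpos + seg_len] = list(
                    scaffold.sequence[vpos : vpos + seg_len]
                )
                segments.append((sid, host_id, vpos + 1, hpos + 1, seg_len))

    paths = {
        "spacers": outdir / "spacers.fasta",
        "viral_trnas": outdir / "viral_trnas.fasta",
        "host_trnas": outdir / "host_trnas.fasta",
        "host_genomes": outdir / "host_genomes.fasta",
        "segments": outdir / "segments.tsv",
        "hosts": outdir / "hosts.tsv",
    }
    write_fasta(spacers, paths["spacers"])
    write_fasta(viral_trnas, paths["viral_trnas"])
    write_fasta(host_trnas, paths["host_trnas"])
    write_fasta([(h, "".join(host_genomes[h])) for h in sorted(host_genomes)],
                paths["host_genomes"])
    with open(paths["segments"], "w") as fh:
        fh.write("viral_scaffold\thost_id\tviral_start\thost_start\tlength\n")
        for row in segments:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(paths["hosts"], "w") as fh:
        fh.write("host_id\tphylum\tgenus\n")
        for host_id in sorted(hosts_seen):
            t = hosts_seen[host_id]
            fh.write(f"{host_id}\t{t.get('phylum', '.')}\t{t.get('genus', '.')}\n")
    return paths
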