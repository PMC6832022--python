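"""End-to-end orchestration: simulate -> classify -> annotate -> abundance
-> microdiversity, with a run manifest for reproducibility.

Stages communicate only through their documented file interfaces (FASTA,
GFF3, SAM, TSV); the manifest records the full threshold configuration,
seeds, input checksums and per-stage row counts, so an identical
config+seed reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path

import yaml

from . import __version__
from .abundance import count_reads, relative_abundance, shannon, subsample_reads
from .annotate import (
    assign_category,
    closest_relative,
    consensus_host,
    default_keyword_table,
    detect_homology,
    match_spacers,
    shared_trnas,
)
from .classify import classify_community, cluster_populations
from .config import PipelineConfig
from .io import (
    read_fasta,
    read_gff3,
    read_hits_table,
    read_id_list,
    read_quotient_table,
    read_sam,
)
from .microdiversity import (
    call_variants,
    category_medians,
    gene_microdiversity,
    pileup_codons,
)
from .model import Scaffold
from .synthetic import (
    CommunityConfig,
    MicrodivSpec,
    emit_host_fixtures,
    generate_community,
    simulate_reads,
    write_reads_sam,
)

logger = logging.getLogger("virodiv")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "outdir" not in data:
        raise ValueError("run config must set 'outdir'")
    for key in data.get("inputs", {}).values():
        if not Path(key).exists():
            raise ValueError(f"input file does not exist: {key}")
    return data


def run_pipeline(config_path: str | Path) -> Path:
    """Execute the full pipeline from a YAML run config; returns outdir.

    The config must validate before any stage runs: unknown threshold keys
    and missing input files abort immediately.
    """
    data = _load_run_config(config_path)
    outdir = Path(data["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(data.get("seed", 0))
    thresholds = PipelineConfig.from_dict(data.get("thresholds", {}))
    thresholds.seed = seed
    thresholds.log_thresholds()

    manifest: dict = {
        "tool": "virodiv",
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in data.items() if k != "outdir"},
        "thresholds": thresholds.to_dict(),
        "stages": {},
        "checksums": {},
    }

    sim_dir = outdir / "sim"
    community_kwargs = dict(data.get("community", {}))
    for tuple_key in ("scaffold_length", "genes_per_scaffold", "gene_length_aa"):
        if tuple_key in community_kwargs:
            community_kwargs[tuple_key] = tuple(community_kwargs[tuple_key])
    ccfg = CommunityConfig(seed=seed, **community_kwargs)
    bundle = generate_community(ccfg, sim_dir)
    fixture_paths = emit_host_fixtures(bundle.truth, bundle.scaffolds, sim_dir, seed=seed)

    md = dict(data.get("microdiv", {}))
    n_sim_genes = int(md.pop("n_genes", 4))
    if "freq_range" in md:
        md["freq_range"] = tuple(md["freq_range"])
    spec = MicrodivSpec(seed=seed, **md)
    viral_sids = sorted(
        s for s, t in bundle.truth.scaffolds.items() if t.planted_class != "nonviral"
    )
    # one gene per viral scaffold until n_sim_genes reached
    reads = []
    sim_genes = []
    for sid in viral_sids:
        if len(sim_genes) >= n_sim_genes:
            break
        sim_genes.append(bundle.genes_by_scaffold[sid][0])
    for gene in sim_genes:
        scaffold_seq = bundle.scaffolds[gene.scaffold_id].sequence
        gene_spec = dataclasses.replace(
            spec,
            n_variant_sites=min(spec.n_variant_sites, gene.n_codons - 2),
        )
        gene_reads, _kept = simulate_reads(gene, scaffold_seq, gene_spec)
        reads.extend(gene_reads)
    sam_path = sim_dir / "reads.sam"
    write_reads_sam(reads, bundle.scaffolds, sam_path)
    manifest["stages"]["simulate"] = {
        "n_scaffolds": len(bundle.scaffolds),
        "n_genes": sum(len(g) for g in bundle.genes_by_scaffold.values()),
        "n_reads": len(reads),
        "n_sim_genes": len(sim_genes),
    }

    classification_path = classify_stage(
        scaffolds_fasta=sim_dir / "scaffolds.fasta",
        genes_gff3=sim_dir / "genes.gff3",
        pvog_hits_tsv=sim_dir / "pvog_hits.tsv",
        quotients_tsv=sim_dir / "quotients.tsv",
        bait_hits_tsv=sim_dir / "bait_hits.tsv",
        out=outdir / "classification.tsv",
        config=thresholds,
        sample_id=ccfg.sample_id,
    )
    manifest["stages"]["classify"] = {
        "rows": sum(1 for _ in open(classification_path)) - 1
    }

    annotation_path = annotate_stage(
        scaffolds_fasta=sim_dir / "scaffolds.fasta",
        genes_gff3=sim_dir / "genes.gff3",
        ref_hits_tsv=sim_dir / "ref_hits.tsv",
        spacers_fasta=fixture_paths["spacers"],
        host_genomes_fasta=fixture_paths["host_genomes"],
        viral_trnas_fasta=fixture_paths["viral_trnas"],
        host_trnas_fasta=fixture_paths["host_trnas"],
        hosts_tsv=fixture_paths["hosts"],
        out=outdir / "annotation.tsv",
        config=thresholds,
    )
    manifest["stages"]["annotate"] = {
        "rows": sum(1 for _ in open(annotation_path)) - 1
    }

    abundance_path = abundance_stage(
        sam_path=sam_path,
        out=outdir / "abundance.tsv",
        sample_id=ccfg.sample_id,
        fraction="viral",
        subsample_n=thresholds.subsample_n,
        seed=seed,
    )
    manifest["stages"]["abundance"] = {
        "rows": sum(1 for _ in open(abundance_path)) - 1
    }

    genes_path, medians_path = microdiv_stage(
        sam_path=sam_path,
        genes_gff3=sim_dir / "genes.gff3",
        scaffolds_fasta=sim_dir / "scaffolds.fasta",
        out_genes=outdir / "microdiv_genes.tsv",
        out_medians=outdir / "microdiv_medians.tsv",
        sample_id=ccfg.sample_id,
        fraction="viral",
        config=thresholds,
    )
    manifest["stages"]["microdiversity"] = {
        "gene_rows": sum(1 for _ in open(genes_path)) - 1,
        "median_rows": sum(1 for _ in open(medians_path)) - 1,
    }

    for f in sorted(sim_dir.iterdir()):
        manifest["checksums"][f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


# ---------------------------------------------------------------------------
# Individual stages (file in -> file out)

def classify_stage(scaffolds_fasta, genes_gff3, pvog_hits_tsv, quotients_tsv,
                   out, bait_hits_tsv=None, curated_txt=None, labels_tsv=None,
                   config: PipelineConfig | None = None, sample_id: str = "") -> Path:
    cfg = config or PipelineConfig()
    records = read_fasta(scaffolds_fasta)
    scaffolds = {
        sid: Scaffold(id=sid, sample_id=sample_id, sequence=seq)
        for sid, seq in records
        if len(seq) >= cfg.min_scaffold_length
    }
    dropped = len(records) - len(scaffolds)
    if dropped:
        logger.info("classify: %d scaffolds below %d bp discarded",
                    dropped, cfg.min_scaffold_length)
    genes = read_gff3(genes_gff3)
    genes_by_scaffold: dict[str, list] = defaultdict(list)
    for g in genes:
        if g.scaffold_id in scaffolds:
            genes_by_scaffold[g.scaffold_id].append(g)
    pvog_hits = read_hits_table(pvog_hits_tsv, subject_kind="og")
    quotients = read_quotient_table(quotients_tsv)
    bait_hits = (read_hits_table(bait_hits_tsv, subject_kind="viral_scaffold_orf")
                 if bait_hits_tsv else None)
    curated = read_id_list(curated_txt) if curated_txt else None

    avq_results, bait_results = classify_community(
        scaffolds, dict(genes_by_scaffold), pvog_hits, quotients,
        bait_hits=bait_hits, curated_ids=curated,
        avq_kwargs=dict(min_percent=cfg.avq.min_percent, min_avq=cfg.avq.min_avq,
                        max_evalue=cfg.avq.max_evalue),
        bait_config=cfg.bait,
    )
    viral = [s for s in scaffolds.values() if s.classification.is_viral]
    populations = cluster_populations(viral, cfg.population) if viral else {}

    out = Path(out)
    with open(out, "w") as fh:
        fh.write("scaffold_id\tn_orfs\tpercent_hit\tavq\tclassification\t"
                 "bait_scaffold\tpopulation_id\n")
        for sid in sorted(scaffolds):
            avq = avq_results.get(sid)
            bait = bait_results.get(sid)
            fh.write("\t".join([
                sid,
                str(avq.n_orfs if avq else len(genes_by_scaffold.get(sid, []))),
                f"{avq.percent_hit:.1f}" if avq else ".",
                f"{avq.avq:.3f}" if avq else ".",
                scaffolds[sid].classification.value,
                (bait.best_bait_scaffold or ".") if bait else ".",
                populations.get(sid, "."),
            ]) + "\n")
    return out


def annotate_stage(scaffolds_fasta, genes_gff3, ref_hits_tsv, out,
                   spacers_fasta=None, host_genomes_fasta=None,
                   viral_trnas_fasta=None, host_trnas_fasta=None,
                   hosts_tsv=None, keywords_tsv=None,
                   config: PipelineConfig | None = None) -> Path:
    from .io import read_keyword_table

    cfg = config or PipelineConfig()
    scaffolds = dict(read_fasta(scaffolds_fasta))
    genes = read_gff3(genes_gff3)
    genes_by_scaffold: dict[str, list] = defaultdict(list)
    for g in genes:
        genes_by_scaffold[g.scaffold_id].append(g)
    ref_hits = read_hits_table(ref_hits_tsv, subject_kind="reference_protein")
    keywords = (read_keyword_table(keywords_tsv) if keywords_tsv
                else default_keyword_table())
    for g in genes:
        g.category_broad, _spec = assign_category(g.category_specific, keywords)

    host_taxonomy: dict[str, dict[str, str]] = {}
    if hosts_tsv:
        with open(hosts_tsv) as fh:
            next(fh)
            for line in fh:
                host_id, phylum, genus = line.rstrip("\n").split("\t")
                host_taxonomy[host_id] = {"phylum": phylum, "genus": genus}

    def _tagged_fasta(path, tag):
        if not path:
            return []
        out_records = []
        for rid, seq in read_fasta(path):
            attrs = dict(kv.split("=", 1) for kv in rid.split("|")[1:] if "=" in kv)
            out_records.append((rid, seq, attrs.get(tag)))
        return out_records

    spacers = [
        (attrs, seq, host_taxonomy.get(attrs, {}))
        for _rid, seq, attrs in _tagged_fasta(spacers_fasta, "host")
        if attrs
    ]
    viral_trnas_all = _tagged_fasta(viral_trnas_fasta, "scaffold")
    host_trnas = [
        (attrs, seq, host_taxonomy.get(attrs, {}))
        for _rid, seq, attrs in _tagged_fasta(host_trnas_fasta, "host")
        if attrs
    ]
    host_genomes = dict(read_fasta(host_genomes_fasta)) if host_genomes_fasta else {}

    out = Path(out)
    with open(out, "w") as fh:
        fh.write("scaffold_id\tfamily\tgenus\tspecies\thost_genus\thost_phylum\t"
                 "signals\n")
        for sid in sorted(scaffolds):
            sgenes = genes_by_scaffold.get(sid, [])
            if not sgenes:
                continue
            calls = {
                rank: closest_relative(sgenes, ref_hits, rank, cfg.taxonomy)
                for rank in ("family", "genus", "species")
            }
            signals = []
            signals += match_spacers(spacers, sid, scaffolds[sid], cfg.host)
            signals += shared_trnas(
                [(rid, seq) for rid, seq, scaf in viral_trnas_all if scaf == sid],
                host_trnas, sid,
            )
            for host_id, hseq in host_genomes.items():
                sig = detect_homology(sid, scaffolds[sid], host_id, hseq,
                                      host_taxonomy.get(host_id, {}), cfg.host)
                if sig:
                    signals.append(sig)
            host_genus = consensus_host(signals, "genus")
            host_phylum = consensus_host(signals, "phylum")
            fh.write("\t".join([
                sid,
                calls["family"].taxon or ".",
                calls["genus"].taxon or ".",
                calls["species"].taxon or ".",
                host_genus or ".",
                host_phylum or ".",
                ",".join(sorted({s.signal for s in signals})) or ".",
            ]) + "\n")
    return out


def abundance_stage(sam_path, out, sample_id="", fraction="viral",
                    subsample_n=None, seed=0, total_reads=None) -> Path:
    alignments = read_sam(sam_path, sample_id=sample_id, fraction=fraction)
    if subsample_n:
        alignments = subsample_reads(alignments, subsample_n, seed)
    counts = count_reads(alignments)
    total = total_reads if total_reads is not None else sum(counts.values())
    percents = relative_abundance(counts, total)
    h = shannon(list(counts.values())) if counts else float("nan")
    out = Path(out)
    with open(out, "w") as fh:
        fh.write(f"# sample={sample_id} fraction={fraction} total_reads={total} "
                 f"shannon={h:.4f}\n")
        fh.write("scaffold_id\tmapped_reads\trelative_abundance_percent\n")
        for sid in sorted(counts):
            fh.write(f"{sid}\t{counts[sid]}\t{percents[sid]:.4f}\n")
    return out


def microdiv_stage(sam_path, genes_gff3, scaffolds_fasta, out_genes, out_medians,
                   sample_id="", fraction="viral",
                   config: PipelineConfig | None = None) -> tuple[Path, Path]:
    cfg = config or PipelineConfig()
    scaffolds = dict(read_fasta(scaffolds_fasta))
    genes = read_gff3(genes_gff3)
    keywords = default_keyword_table()
    alignments = read_sam(sam_path, sample_id=sample_id, fraction=fraction)
    by_scaffold: dict[str, list] = defaultdict(list)
    for a in alignments:
        by_scaffold[a.scaffold_id].append(a)

    stats = []
    for gene in genes:
        alns = by_scaffold.get(gene.scaffold_id)
        if not alns or gene.scaffold_id not in scaffolds:
            continue
        gene.category_broad, gene.category_specific = assign_category(
            gene.category_specific, keywords
        )
        columns = pileup_codons(alns, gene, scaffolds[gene.scaffold_id])
        if not any(col.coverage for col in columns):
            continue
        calls = call_variants(columns, cfg.snp)
        gm = gene_microdiversity(calls, columns, gene,
                                 scaffolds[gene.scaffold_id], cfg.snp)
        gm.sample_id = sample_id
        gm.fraction = fraction
        stats.append(gm)

    out_genes = Path(out_genes)
    with open(out_genes, "w") as fh:
        fh.write("gene_id\tsample\tfraction\tcategory_broad\tcategory_specific\t"
                 "obs_n\tobs_s\tf_n\tf_s\tp_n\tp_s\tpnps\tn_polymorphic\t"
                 "n_assayable\tpercent_polymorphic\tmean_coverage\n")
        for g in stats:
            fmt = lambda v: f"{v:.4f}" if v is not None else "."
            fh.write("\t".join([
                g.gene_id, g.sample_id, g.fraction, g.category_broad,
                g.category_specific, str(g.obs_n), str(g.obs_s),
                f"{g.f_n:.4f}", f"{g.f_s:.4f}", fmt(g.p_n), fmt(g.p_s),
                fmt(g.pnps), str(g.n_polymorphic), str(g.n_assayable),
                f"{g.percent_polymorphic:.2f}", f"{g.mean_coverage:.1f}",
            ]) + "\n")

    medians = category_medians(stats)
    out_medians = Path(out_medians)
    with open(out_medians, "w") as fh:
        fh.write("sample\tfraction\tcategory\tn_genes\tn_pnps_genes\t"
                 "median_pnps\tmedian_percent_polymorphic\n")
        for row in medians:
            fh.write("\t".join([
                str(row["sample_id"]), str(row["fraction"]),
                str(row["category_broad"]), str(row["n_genes"]),
                str(row["n_pnps_genes"]),
                f"{row['median_pnps']:.4f}" if row["median_pnps"] is not None else ".",
                (f"{row['median_percent_polymorphic']:.2f}"
                 if row["median_percent_polymorphic"] is not None else "."),
            ]) + "\n")
    return out_genes, out_medians
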