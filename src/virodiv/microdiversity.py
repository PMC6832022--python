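"""Codon-resolved microdiversity: pileups, SNP filters, pN/pS summaries.

A read contributes to a codon only when a single aligned block covers all
three of its bases (indels or clips inside the codon exclude the read).
Candidate codon mutations are valid only when seen at least ``min_count``
times, in at least ``min_freq`` of the reads covering the codon, and at a
codon coverage of at least ``min_cov`` (all thresholds inclusive). Valid
mutations feed the percentage of polymorphic sites and pN/pS, the observed
nonsynonymous:synonymous counts normalised by the gene's neutral-model
opportunity fractions.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict

import numpy as np
from scipy import stats

from .codon import (
    STOP_CODONS,
    gene_neutral_fractions,
    is_includable,
    reverse_complement,
    translate_codon,
)
from .config import SnpConfig
from .model import CodonColumn, Gene, GeneMicrodiversity, ReadAlignment, VariantCall

logger = logging.getLogger("virodiv")


def _codon_genomic_positions(gene: Gene, codon_index: int) -> tuple[int, int, int]:
    """1-based scaffold positions of a codon's three bases, ascending order.

    For minus-strand genes codon 0 sits at the gene's genomic end; the bases
    are still returned in ascending genomic order and reverse-complemented
    at extraction time.
    """
    if gene.strand == "+":
        p = gene.start + 3 * codon_index
        return p, p + 1, p + 2
    p = gene.end - 3 * codon_index
    return p - 2, p - 1, p


def _read_codon(aln: ReadAlignment, positions: tuple[int, int, int], strand: str
                ) -> str | None:
    """Read codon in gene orientation iff one block spans all three bases."""
    p_lo, _p_mid, p_hi = positions
    for roff, rpos, length in aln.blocks:
        if rpos <= p_lo and p_hi < rpos + length:
            raw = aln.sequence[roff + (p_lo - rpos) : roff + (p_lo - rpos) + 3]
            return raw if strand == "+" else reverse_complement(raw)
    return None


def pileup_codons(alignments: list[ReadAlignment], gene: Gene,
                  scaffold_sequence: str) -> list[CodonColumn]:
    """Per-codon pileup over the gene, in gene orientation.

    Read codons containing N are ignored entirely (N never counts as a
    variant base, nor toward coverage).
    """
    coding = gene.coding_sequence(scaffold_sequence)
    n_codons = len(coding) // 3
    span_lo, span_hi = gene.start, gene.end
    relevant = [
        a for a in alignments
        if a.scaffold_id == gene.scaffold_id
        and a.blocks[0][1] <= span_hi
        and a.blocks[-1][1] + a.blocks[-1][2] - 1 >= span_lo
    ]
    columns = []
    for ci in range(n_codons):
        ref_codon = coding[3 * ci : 3 * ci + 3]
        positions = _codon_genomic_positions(gene, ci)
        coverage = 0
        variants: dict[str, int] = defaultdict(int)
        for aln in relevant:
            codon = _read_codon(aln, positions, gene.strand)
            if codon is None or "N" in codon:
                continue
            coverage += 1
            if codon != ref_codon:
                variants[codon] += 1
        columns.append(CodonColumn(
            gene_id=gene.id,
            codon_index=ci,
            ref_codon=ref_codon,
            coverage=coverage,
            variant_counts=dict(sorted(variants.items())),
        ))
    return columns


def call_variants(columns: list[CodonColumn], config: SnpConfig | None = None
                  ) -> list[VariantCall]:
    """Apply the three validity filters to every candidate codon mutation.

    Columns whose reference codon is a stop or contains N are excluded
    entirely. Effect is synonymous when the variant codon translates to the
    reference amino acid; stop-gains count as nonsynonymous.
    """
    cfg = config or SnpConfig()
    calls = []
    for col in columns:
        if not is_includable(col.ref_codon):
            continue
        ref_aa = translate_codon(col.ref_codon)
        for variant, count in col.variant_counts.items():
            aa = translate_codon(variant)
            if aa is None:
                continue
            valid = (
                count >= cfg.min_count
                and count / col.coverage >= cfg.min_freq
                and col.coverage >= cfg.min_cov
            )
            calls.append(VariantCall(
                gene_id=col.gene_id,
                codon_index=col.codon_index,
                ref_codon=col.ref_codon,
                variant_codon=variant,
                count=count,
                coverage=col.coverage,
                effect="synonymous" if aa == ref_aa else "nonsynonymous",
                valid=valid,
            ))
    return calls


def gene_microdiversity(
    calls: list[VariantCall],
    columns: list[CodonColumn],
    gene: Gene,
    scaffold_sequence: str,
    config: SnpConfig | None = None,
) -> GeneMicrodiversity:
    """Per-gene polymorphism summary from validated variant calls.

    Observed counts are distinct valid variant alleles per codon by default
    (``count_mode="reads"`` weights each allele by its read count instead).
    Assayable codons are includable reference codons at coverage >= min_cov.
    """
    cfg = config or SnpConfig()
    coding = gene.coding_sequence(scaffold_sequence)
    f_n, f_s = gene_neutral_fractions(coding)

    valid = [c for c in calls if c.valid]
    weight = (lambda c: c.count) if cfg.count_mode == "reads" else (lambda c: 1)
    obs_n = sum(weight(c) for c in valid if c.effect == "nonsynonymous")
    obs_s = sum(weight(c) for c in valid if c.effect == "synonymous")
    polymorphic_codons = {c.codon_index for c in valid}
    assayable = [
        col for col in columns
        if is_includable(col.ref_codon) and col.coverage >= cfg.min_cov
    ]
    mean_cov = float(np.mean([col.coverage for col in columns])) if columns else 0.0
    return GeneMicrodiversity(
        gene_id=gene.id,
        category_broad=gene.category_broad,
        category_specific=gene.category_specific,
        obs_n=obs_n,
        obs_s=obs_s,
        f_n=f_n,
        f_s=f_s,
        n_polymorphic=len(polymorphic_codons),
        n_assayable=len(assayable),
        mean_coverage=mean_cov,
    )


def category_medians(
    gene_stats: list[GeneMicrodiversity],
    group_keys: tuple[str, ...] = ("sample_id", "fraction", "category_broad"),
    min_genes: int = 3,
) -> list[dict]:
    """Group medians of pN/pS and percent polymorphic sites.

    For pN/pS medians a gene qualifies only with pN > 0 AND pS > 0, at least
    one polymorphic site, and >= 1% polymorphic sites; groups with fewer
    than ``min_genes`` qualifying genes report no pN/pS median.
    Percent-polymorphic medians are computed over all genes with at least
    one assayable codon.
    """
    groups: dict[tuple, list[GeneMicrodiversity]] = defaultdict(list)
    for g in gene_stats:
        groups[tuple(getattr(g, k) for k in group_keys)].append(g)
    rows = []
    for key in sorted(groups):
        members = groups[key]
        qualifying = [
            g.pnps for g in members
            if g.p_n is not None and g.p_n > 0
            and g.p_s is not None and g.p_s > 0
            and g.n_polymorphic >= 1 and g.percent_polymorphic >= 1.0
            and g.pnps is not None
        ]
        assayed = [g.percent_polymorphic for g in members if g.n_assayable >= 1]
        row = dict(zip(group_keys, key))
        row["n_genes"] = len(members)
        row["n_pnps_genes"] = len(qualifying)
        row["median_pnps"] = (
            float(np.median(qualifying)) if len(qualifying) >= min_genes else None
        )
        row["median_percent_polymorphic"] = (
            float(np.median(assayed)) if assayed else None
        )
        rows.append(row)
    return rows


def consensus_profile(columns: list[CodonColumn], config: SnpConfig | None = None
                      ) -> list[dict]:
    """Per-codon consensus amino-acid frequency with polymorphic flags.

    The consensus is the most frequent amino acid among the spanning reads'
    codons (ties resolve to the reference amino acid); the frequency is its
    read share. A site is flagged polymorphic when it carries at least one
    valid variant call.
    """
    calls = call_variants(columns, config)
    polymorphic = {c.codon_index for c in calls if c.valid}
    profile = []
    for col in columns:
        if col.coverage == 0:
            profile.append({
                "codon_index": col.codon_index, "consensus_aa": None,
                "frequency": None, "polymorphic": False,
            })
            continue
        ref_aa = translate_codon(col.ref_codon)
        aa_counts: Counter[str] = Counter()
        n_ref_reads = col.coverage - sum(col.variant_counts.values())
        if ref_aa is not None:
            aa_counts[ref_aa] += n_ref_reads
        for variant, count in col.variant_counts.items():
            aa = translate_codon(variant)
            if aa is not None:
                aa_counts[aa] += count
        top = max(aa_counts.values())
        leaders = {aa for aa, c in aa_counts.items() if c == top}
        consensus = ref_aa if ref_aa in leaders else sorted(leaders)[0]
        profile.append({
            "codon_index": col.codon_index,
            "consensus_aa": consensus,
            "frequency": aa_counts[consensus] / col.coverage,
            "polymorphic": col.codon_index in polymorphic,
        })
    return profile


def coverage_correlation(
    gene_stats: list[GeneMicrodiversity],
    metric: str = "percent_polymorphic",
) -> float | None:
    """Pearson correlation between gene mean coverage and a diversity metric.

    ``metric`` is ``percent_polymorphic`` or ``pnps``; genes where the
    metric is undefined are dropped. Returns None for degenerate inputs
    (fewer than 3 genes or zero variance).
    """
    pairs = [
        (g.mean_coverage, getattr(g, "pnps" if metric == "pnps" else metric))
        for g in gene_stats
    ]
    pairs = [(x, y) for x, y in pairs if y is not None]
    if len(pairs) < 3:
        return None
    x, y = np.array(pairs).T
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r, _p = stats.pearsonr(x, y)
    return float(r)
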