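"""Shared data model for the virome analysis pipeline.

Coordinates are 1-based inclusive throughout (GFF3/SAM convention);
conversion to 0-based happens only at array boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Classification(str, enum.Enum):
    """Viral-identification state of a scaffold.

    Transitions only ever go from ``unclassified`` to one of the terminal
    states (three identification rounds or non-viral).
    """

    unclassified = "unclassified"
    viral_round1 = "viral_round1"
    viral_round2 = "viral_round2"
    viral_curated = "viral_curated"
    nonviral = "nonviral"

    @property
    def is_viral(self) -> bool:
        return self.value.startswith("viral")


#: taxonomic ranks used for closest-relative affiliation
RANKS = ("family", "genus", "species")


@dataclass
class Scaffold:
    """An assembled genomic sequence with its classification state."""

    id: str
    sample_id: str
    sequence: str
    classification: Classification = Classification.unclassified
    taxonomy: dict[str, str] = field(default_factory=dict)
    host: dict[str, str] | None = None
    population_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def set_classification(self, new: Classification) -> None:
        """Apply a classification transition (unclassified -> terminal only)."""
        if self.classification is not Classification.unclassified and new != self.classification:
            raise ValueError(
                f"scaffold {self.id}: illegal transition "
                f"{self.classification.value} -> {new.value}"
            )
        self.classification = new


@dataclass
class Gene:
    """A protein-coding ORF on a scaffold.

    ``start``/``end`` are 1-based inclusive on the scaffold; for minus-strand
    genes the coding sequence is the reverse complement of
    ``scaffold[start..end]`` and all codon indices are in gene orientation.
    """

    id: str
    scaffold_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    protein: str = ""
    category_broad: str = "unknown"
    category_specific: str = "unknown"
    pvog_hit: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"gene {self.id}: invalid coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: invalid strand {self.strand!r}")

    @property
    def n_codons(self) -> int:
        return (self.end - self.start + 1) // 3

    def coding_sequence(self, scaffold_sequence: str) -> str:
        from .codon import reverse_complement

        seg = scaffold_sequence[self.start - 1 : self.end]
        return seg if self.strand == "+" else reverse_complement(seg)


@dataclass
class ProteinHit:
    """One row of a tabular protein search result (outfmt-6-like)."""

    query_gene_id: str
    subject_id: str
    percent_identity: float
    aln_length_aa: int
    bitscore: float
    evalue: float
    subject_kind: str = "og"  # og | viral_scaffold_orf | reference_protein
    subject_taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_gene_id}->{self.subject_id}: negative E value")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"hit {self.query_gene_id}->{self.subject_id}: identity out of [0,100]"
            )


@dataclass
class ReadAlignment:
    """A mapped read as non-overlapping matched blocks.

    Each block is ``(read_offset_0based, ref_pos_1based, length)``; only
    aligned (M/=/X) runs appear, so every pileup base consumed downstream lies
    inside a declared block. ``score`` carries the aligner score (AS tag) when
    present, for best-alignment read assignment.
    """

    read_id: str
    scaffold_id: str
    blocks: list[tuple[int, int, int]]
    sequence: str
    sample_id: str = ""
    fraction: str = "viral"  # viral | cellular
    score: float | None = None

    def reference_span(self) -> tuple[int, int]:
        return self.blocks[0][1], self.blocks[-1][1] + self.blocks[-1][2] - 1

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned to a 1-based reference position, or None."""
        for roff, rpos, length in self.blocks:
            if rpos <= ref_pos < rpos + length:
                return self.sequence[roff + (ref_pos - rpos)]
        return None


@dataclass
class AvqResult:
    """Round-1 added-viral-quotient screen result for one scaffold."""

    scaffold_id: str
    n_orfs: int
    n_orfs_with_pvog_hit: int
    avq: float
    passed_round1: bool

    @property
    def percent_hit(self) -> float:
        return 100.0 * self.n_orfs_with_pvog_hit / self.n_orfs


@dataclass
class BaitResult:
    """Round-2 protein-baiting result for one candidate scaffold."""

    scaffold_id: str
    n_orfs: int
    best_bait_scaffold: str | None
    n_matched_to_best: int
    recruited: bool

    @property
    def percent_matched(self) -> float:
        return 100.0 * self.n_matched_to_best / self.n_orfs


@dataclass
class TaxonomyCall:
    """Closest-relative taxonomy at one rank."""

    scaffold_id: str
    rank: str
    taxon: str | None
    n_orfs_matched_to_taxon: int
    mean_identity: float | None
    tie_broken: bool = False


@dataclass
class HostSignal:
    """One automated virus-host linkage signal."""

    viral_scaffold_id: str
    host_id: str
    host_taxonomy: dict[str, str]
    signal: str  # homology | crispr | trna
    score: float

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("host signal score must be > 0")


@dataclass
class CodonColumn:
    """Per-codon pileup: reads fully spanning all three bases of one codon."""

    gene_id: str
    codon_index: int
    ref_codon: str
    coverage: int
    variant_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class VariantCall:
    """A candidate codon mutation with its three-filter validity verdict."""

    gene_id: str
    codon_index: int
    ref_codon: str
    variant_codon: str
    count: int
    coverage: int
    effect: str  # synonymous | nonsynonymous
    valid: bool

    @property
    def frequency(self) -> float:
        return self.count / self.coverage


@dataclass
class GeneMicrodiversity:
    """Per-gene polymorphism summary.

    pN and pS are the observed nonsynonymous/synonymous mutation counts each
    divided by its expected share under the uniform single-substitution
    neutral model (f_N, f_S with f_N + f_S = 1); their ratio pN/pS is the
    population-level analogue of dN/dS.
    """

    gene_id: str
    category_broad: str
    category_specific: str
    obs_n: int
    obs_s: int
    f_n: float
    f_s: float
    n_polymorphic: int
    n_assayable: int
    mean_coverage: float
    sample_id: str = ""
    fraction: str = "viral"

    @property
    def p_n(self) -> float | None:
        total = self.obs_n + self.obs_s
        if total == 0 or self.f_n == 0:
            return None
        return self.obs_n / (total * self.f_n)

    @property
    def p_s(self) -> float | None:
        total = self.obs_n + self.obs_s
        if total == 0 or self.f_s == 0:
            return None
        return self.obs_s / (total * self.f_s)

    @property
    def pnps(self) -> float | None:
        if self.obs_s == 0 or self.obs_n + self.obs_s == 0 or self.f_n == 0 or self.f_s == 0:
            return None
        return (self.obs_n / self.obs_s) * (self.f_s / self.f_n)

    @property
    def percent_polymorphic(self) -> float:
        if self.n_assayable == 0:
            return 0.0
        return 100.0 * self.n_polymorphic / self.n_assayable


@dataclass
class AbundanceProfile:
    """Per-sample, per-fraction mapped-read relative abundances."""

    sample_id: str
    fraction: str
    total_reads: int
    counts: dict[str, int]

    @property
    def relative_abundance(self) -> dict[str, float]:
        from .abundance import relative_abundance

        return relative_abundance(self.counts, self.total_reads)

    @property
    def shannon(self) -> float:
        from .abundance import shannon

        return shannon(list(self.counts.values()))
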