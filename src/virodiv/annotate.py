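"""Closest-relative taxonomy, functional categories, and host prediction.

Taxonomy follows a majority vote over the ORFs' best reference hits at each
rank independently; ties go to the taxon with the highest mean identity
among its matched ORFs. Host prediction combines three automated signals —
long high-identity genomic homology, CRISPR spacer matches, and shared tRNA
genes — and discards scaffolds whose signals point to more than one taxon.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from importlib import resources

import numpy as np

from .codon import reverse_complement
from .config import HostConfig, TaxonomyConfig
from .model import Gene, HostSignal, ProteinHit, TaxonomyCall

logger = logging.getLogger("virodiv")


# ---------------------------------------------------------------------------
# Taxonomy

def closest_relative(
    genes: list[Gene],
    hits: list[ProteinHit],
    rank: str,
    config: TaxonomyConfig | None = None,
) -> TaxonomyCall:
    """Majority-vote closest relative for one scaffold at one rank."""
    cfg = config or TaxonomyConfig()
    if not genes:
        raise ValueError("closest_relative requires at least one ORF")
    scaffold_id = genes[0].scaffold_id
    gene_ids = {g.id for g in genes}

    passing: dict[str, list[ProteinHit]] = defaultdict(list)
    for h in hits:
        if (
            h.query_gene_id in gene_ids
            and h.percent_identity >= cfg.min_identity
            and h.bitscore >= cfg.min_bitscore
            and h.aln_length_aa >= cfg.min_aln_len
            and h.evalue <= cfg.max_evalue
        ):
            passing[h.query_gene_id].append(h)

    votes: dict[str, list[float]] = defaultdict(list)  # taxon -> identities
    for gene_hits in passing.values():
        best = min(gene_hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        taxon = (best.subject_taxonomy or {}).get(rank)
        if taxon:
            votes[taxon].append(best.percent_identity)

    if not votes:
        return TaxonomyCall(scaffold_id, rank, None, 0, None)
    max_count = max(len(v) for v in votes.values())
    leaders = sorted(t for t, v in votes.items() if len(v) == max_count)
    tie = len(leaders) > 1
    winner = max(leaders, key=lambda t: (float(np.mean(votes[t])), t))
    return TaxonomyCall(
        scaffold_id=scaffold_id,
        rank=rank,
        taxon=winner,
        n_orfs_matched_to_taxon=max_count,
        mean_identity=float(np.mean(votes[winner])),
        tie_broken=tie,
    )


# ---------------------------------------------------------------------------
# Functional categories

def default_keyword_table() -> list[tuple[str, str, str]]:
    """The packaged functional-category keyword table, priority-ordered."""
    rows = []
    text = resources.files("virodiv.data").joinpath("keywords.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        kw, broad, specific = line.split("\t")
        rows.append((kw, broad, specific))
    return rows


def assign_category(
    product: str, keyword_table: list[tuple[str, str, str]]
) -> tuple[str, str]:
    """First case-insensitive substring match wins; no match -> unknown."""
    lowered = product.lower()
    for keyword, broad, specific in keyword_table:
        if keyword.lower() in lowered:
            return broad, specific
    return "unknown", "unknown"


# ---------------------------------------------------------------------------
# Host signals

def _best_diagonal_segment(a: str, b: str, k: int) -> tuple[int, int, int, float]:
    """Longest shared segment on the best shared-k-mer diagonal.

    Returns (start_a_0based, start_b_0based, length, percent_identity); the
    segment spans the first to last shared k-mer on the modal diagonal and is
    extended outwards while bases match exactly.
    """
    if len(a) < k or len(b) < k:
        return 0, 0, 0, 0.0
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(a) - k + 1):
        index[a[i : i + k]].append(i)
    spans: dict[int, list[int]] = defaultdict(list)
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            spans[i - j].append(i)
    if not spans:
        return 0, 0, 0, 0.0
    diag = max(spans, key=lambda d: (len(spans[d]), -abs(d)))
    lo = min(spans[diag])
    hi = max(spans[diag]) + k - 1  # inclusive end in a-coordinates
    while lo > 0 and lo - diag > 0 and a[lo - 1] == b[lo - 1 - diag]:
        lo -= 1
    while hi + 1 < len(a) and hi + 1 - diag < len(b) and a[hi + 1] == b[hi + 1 - diag]:
        hi += 1
    length = hi - lo + 1
    matches = sum(1 for i in range(lo, hi + 1) if a[i] == b[i - diag] and a[i] != "N")
    return lo, lo - diag, length, 100.0 * matches / length


def detect_homology(
    viral_scaffold_id: str,
    viral_sequence: str,
    host_id: str,
    host_sequence: str,
    host_taxonomy: dict[str, str],
    config: HostConfig | None = None,
) -> HostSignal | None:
    """Long shared genomic segment between a virus and a candidate host.

    Emits a signal only when the best shared segment reaches ``min_len`` bp
    at ``min_identity`` percent nucleotide identity; the score is the
    segment length in bp.
    """
    cfg = config or HostConfig()
    best = (0, 0.0)
    for seq in (host_sequence, reverse_complement(host_sequence)):
        _, _, length, ident = _best_diagonal_segment(viral_sequence, seq, k=21)
        if (length, ident) > best:
            best = (length, ident)
    length, ident = best
    if length >= cfg.homology_min_len and ident >= cfg.homology_min_identity:
        return HostSignal(viral_scaffold_id, host_id, host_taxonomy, "homology", length)
    return None


def _hamming_occurrences(pattern: str, text: str, max_mismatches: int) -> bool:
    if len(pattern) > len(text):
        return False
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
    mismatches = (windows != p).sum(axis=1)
    return bool((mismatches <= max_mismatches).any())


def match_spacers(
    spacers: list[tuple[str, str, dict[str, str]]],
    scaffold_id: str,
    scaffold_sequence: str,
    config: HostConfig | None = None,
) -> list[HostSignal]:
    """CRISPR spacer matches on either strand with at most one mismatch.

    ``spacers`` are (host_id, spacer_sequence, host_taxonomy) triples;
    spacers shorter than ``spacer_min_len`` are ignored. The score is the
    spacer length.
    """
    cfg = config or HostConfig()
    signals = []
    for host_id, spacer, taxonomy in spacers:
        if len(spacer) < cfg.spacer_min_len:
            logger.warning("spacer from %s shorter than %d bp; skipped",
                           host_id, cfg.spacer_min_len)
            continue
        if _hamming_occurrences(spacer, scaffold_sequence, cfg.spacer_max_mismatches) or \
           _hamming_occurrences(reverse_complement(spacer), scaffold_sequence,
                                cfg.spacer_max_mismatches):
            signals.append(HostSignal(scaffold_id, host_id, taxonomy, "crispr", len(spacer)))
    return signals


def shared_trnas(
    viral_trnas: list[tuple[str, str]],
    host_trnas: list[tuple[str, str, dict[str, str]]],
    scaffold_id: str,
) -> list[HostSignal]:
    """Exact full-length nucleotide identity between viral and host tRNAs.

    ``viral_trnas`` are (trna_id, sequence) for the scaffold; ``host_trnas``
    are (host_id, sequence, host_taxonomy). The score is the tRNA length.
    """
    host_by_seq: dict[str, list[tuple[str, dict[str, str]]]] = defaultdict(list)
    for host_id, seq, taxonomy in host_trnas:
        host_by_seq[seq].append((host_id, taxonomy))
    signals = []
    for _tid, seq in viral_trnas:
        for host_id, taxonomy in host_by_seq.get(seq, ()):
            signals.append(HostSignal(scaffold_id, host_id, taxonomy, "trna", len(seq)))
    return signals


def consensus_host(signals: list[HostSignal], rank: str) -> str | None:
    """Consensus host taxon at a rank; ambiguous predictions are discarded.

    Returns the taxon when every signal agrees at the requested rank, and
    None when there are no signals or the signals disagree (a virus
    predicted to infect more than one taxon).
    """
    taxa = {s.host_taxonomy.get(rank) for s in signals} - {None}
    if len(taxa) == 1:
        return taxa.pop()
    return None
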