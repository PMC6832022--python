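"""Mapped-read relative abundances, aggregation, and Shannon diversity.

Relative abundance of a scaffold is the percentage of the sample's total
reads that map to it (a read counts once, at its best alignment). The
Shannon index H = -sum p_i ln p_i is computed over the renormalised
per-scaffold proportions of mapped reads, in natural log.
"""

from __future__ import annotations

import logging
import random
from collections import defaultdict

import numpy as np

from .model import AbundanceProfile, ReadAlignment

logger = logging.getLogger("virodiv")


def subsample_reads(alignments: list[ReadAlignment], n: int, seed: int
                    ) -> list[ReadAlignment]:
    """Uniform without-replacement subsample of reads (by read id).

    Keeps every alignment of a selected read. If at most ``n`` distinct
    reads are present, all are kept. Deterministic per seed.
    """
    if n <= 0:
        raise ValueError("subsample size must be > 0")
    read_ids = sorted({a.read_id for a in alignments})
    if len(read_ids) <= n:
        return list(alignments)
    keep = set(random.Random(seed).sample(read_ids, n))
    return [a for a in alignments if a.read_id in keep]


def count_reads(alignments: list[ReadAlignment]) -> dict[str, int]:
    """Per-scaffold mapped-read counts, each read counted once.

    A multi-mapped read is assigned to its best-scoring alignment; score
    ties break to the lexicographically first scaffold id.
    """
    by_read: dict[str, list[ReadAlignment]] = defaultdict(list)
    for a in alignments:
        by_read[a.read_id].append(a)
    counts: dict[str, int] = defaultdict(int)
    for alns in by_read.values():
        best = min(alns, key=lambda a: (-(a.score if a.score is not None else 0.0),
                                        a.scaffold_id))
        counts[best.scaffold_id] += 1
    return dict(counts)


def relative_abundance(counts: dict[str, int], total_reads: int) -> dict[str, float]:
    """Percent of the sample's total reads mapped to each scaffold."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if sum(counts.values()) > total_reads:
        raise ValueError("mapped counts exceed total reads")
    return {sid: 100.0 * c / total_reads for sid, c in counts.items()}


def aggregate_by(percents: dict[str, float], key_of: dict[str, str | None]
                 ) -> dict[str, float]:
    """Sum per-scaffold percents into groups (taxon family, host phylum...).

    Scaffolds with no key fall into the "unassigned" bucket; the grand total
    is preserved exactly.
    """
    grouped: dict[str, float] = defaultdict(float)
    for sid, pct in percents.items():
        grouped[key_of.get(sid) or "unassigned"] += pct
    return dict(grouped)


def shannon(abundances: list[float]) -> float:
    """Shannon index H = -sum p ln p over renormalised proportions."""
    arr = np.asarray(abundances, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all abundances are zero")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def fraction_ratio(cellular: dict[str, float], viral: dict[str, float]
                   ) -> tuple[dict[str, float], dict[str, float], int]:
    """Cellular:viral abundance ratio per scaffold, with summary statistics.

    Scaffolds absent (zero) in the viral fraction are excluded and counted.
    Returns (per-scaffold ratios, {median, q1, q3}, n_excluded).
    """
    ratios: dict[str, float] = {}
    n_excluded = 0
    for sid, v_pct in viral.items():
        if v_pct <= 0:
            n_excluded += 1
            continue
        ratios[sid] = cellular.get(sid, 0.0) / v_pct
    for sid in cellular:
        if sid not in viral:
            n_excluded += 1
    if n_excluded:
        logger.info("fraction_ratio: %d scaffolds excluded (absent from viral fraction)",
                    n_excluded)
    values = np.array(sorted(ratios.values()), dtype=float)
    summary = {
        "median": float(np.median(values)) if values.size else float("nan"),
        "q1": float(np.percentile(values, 25)) if values.size else float("nan"),
        "q3": float(np.percentile(values, 75)) if values.size else float("nan"),
    }
    return ratios, summary, n_excluded


def profile_from_alignments(alignments: list[ReadAlignment], sample_id: str,
                            fraction: str, total_reads: int) -> AbundanceProfile:
    return AbundanceProfile(
        sample_id=sample_id,
        fraction=fraction,
        total_reads=total_reads,
        counts=count_reads(alignments),
    )
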