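"""Genetic-code helpers: codon translation and the neutral mutation model.

The neutral model enumerates, for every sense codon, its 9 single-nucleotide
substitutions and classifies each as synonymous (amino acid unchanged) or
nonsynonymous (amino acid changed; stop-gain counts as nonsynonymous).
Summing over a gene's codons gives the neutral opportunity fractions
f_S and f_N used to normalise observed mutation counts into pN and pS.
"""

from __future__ import annotations

import functools
from itertools import product

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

#: codon -> single-letter amino acid, stops as "*" (standard genetic code)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, ``*`` for stops, None if it contains N."""
    return CODON_TO_AA.get(codon)


def is_includable(codon: str) -> bool:
    """True for sense codons over {A,C,G,T}; N-containing and stop codons
    are excluded from all neutral-model totals."""
    return codon in CODON_TO_AA and codon not in STOP_CODONS


def single_nucleotide_neighbors(codon: str) -> list[str]:
    """The 9 codons one substitution away, in a fixed deterministic order."""
    return [
        codon[:i] + b + codon[i + 1 :]
        for i in range(3)
        for b in BASES
        if b != codon[i]
    ]


@functools.lru_cache(maxsize=None)
def neutral_codon_spectrum(codon: str) -> tuple[int, int]:
    """(n_syn, n_nonsyn) over the 9 single-nucleotide substitutions.

    Raises ValueError for stop codons or codons containing non-ACGT
    characters; such codons carry no neutral opportunity and are excluded
    from gene totals by the caller.
    """
    if not is_includable(codon):
        raise ValueError(f"codon {codon!r} is not an includable sense codon")
    aa = CODON_TO_AA[codon]
    n_syn = sum(1 for v in single_nucleotide_neighbors(codon) if CODON_TO_AA[v] == aa)
    return n_syn, 9 - n_syn


def gene_neutral_fractions(coding_sequence: str) -> tuple[float, float]:
    """Neutral opportunity fractions (f_N, f_S) for a coding sequence.

    f_S = sum of synonymous neighbour counts over all includable codons,
    divided by 9 * n_codons_included; f_N = 1 - f_S. Codons containing N and
    stop codons do not contribute.
    """
    if len(coding_sequence) % 3:
        raise ValueError("coding sequence length is not a multiple of 3")
    codons = [coding_sequence[i : i + 3] for i in range(0, len(coding_sequence), 3)]
    included = [c for c in codons if is_includable(c)]
    if not included:
        raise ValueError("gene has no includable codons")
    total_syn = sum(neutral_codon_spectrum(c)[0] for c in included)
    f_s = total_syn / (9 * len(included))
    return 1.0 - f_s, f_s


def all_sense_codons() -> list[str]:
    """The 61 sense codons of the standard code, lexicographic order."""
    return sorted(
        c for c in ("".join(t) for t in product(BASES, repeat=3)) if c not in STOP_CODONS
    )
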