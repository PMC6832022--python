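"""Readers and writers for every standard format the pipeline touches.

FASTA goes through Bio.SeqIO, SAM through pysam; the tab-separated tables
(search hits, OG quotients, functional keywords, external classifier labels)
are fixed-column formats parsed with per-line error reporting.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import Gene, ProteinHit, ReadAlignment, RANKS

logger = logging.getLogger("virodiv")

_VALID_BASES = set("ACGTN")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an order-preserving list of (id, sequence).

    Sequences are upper-cased; characters outside {A,C,G,T,N} are mapped to N
    with a logged warning. A non-empty file whose first record has no header
    raises with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: malformed FASTA header at line {lineno}")
            break
        else:
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not set(seq) <= _VALID_BASES:
            bad = sorted(set(seq) - _VALID_BASES)
            logger.warning(
                "%s: record %s contains non-ACGTN characters %s; mapped to N",
                path, rec.id, "".join(bad),
            )
            seq = "".join(b if b in _VALID_BASES else "N" for b in seq)
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    seqrecs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Protein FASTA: upper-cased, no alphabet coercion."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Tabular search hits (BLAST/DIAMOND/HMMER outfmt-6-like)

#: query, subject, identity, aln_len, mismatches, gaps, qstart, qend,
#: sstart, send, evalue, bitscore
OUTFMT6_NCOL = 12


def read_hits_table(path: str | Path, subject_kind: str = "og") -> list[ProteinHit]:
    """Parse a 12-column tab-separated hits table into ProteinHit records.

    Three optional trailing columns (family, genus, species of the subject)
    are accepted for reference-protein tables. Rows with a wrong column count
    or unparseable numeric fields raise, naming the line.
    """
    path = Path(path)
    hits: list[ProteinHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (OUTFMT6_NCOL, OUTFMT6_NCOL + len(RANKS)):
                raise ValueError(
                    f"{path}: line {lineno}: expected {OUTFMT6_NCOL} columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = ProteinHit(
                    query_gene_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    aln_length_aa=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    subject_kind=subject_kind,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if len(fields) == OUTFMT6_NCOL + len(RANKS):
                tax = {r: v for r, v in zip(RANKS, fields[OUTFMT6_NCOL:]) if v and v != "."}
                hit.subject_taxonomy = tax or None
            hits.append(hit)
    return hits


def write_hits_table(hits: list[ProteinHit], path: str | Path) -> None:
    """Write hits in the 12(+3)-column format read_hits_table accepts.

    Unknown alignment bookkeeping columns (mismatches, gaps, coordinates) are
    emitted as zeros; round-tripping preserves every field the model keeps.
    """
    with_tax = any(h.subject_taxonomy for h in hits)
    with open(path, "w") as fh:
        for h in hits:
            row = [
                h.query_gene_id, h.subject_id, f"{h.percent_identity:.1f}",
                str(h.aln_length_aa), "0", "0", "1", str(h.aln_length_aa),
                "1", str(h.aln_length_aa), f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            ]
            if with_tax:
                tax = h.subject_taxonomy or {}
                row += [tax.get(r, ".") for r in RANKS]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Simple two/three-column tables

def read_quotient_table(path: str | Path) -> dict[str, float]:
    """OG -> viral quotient in [0, 1]."""
    quotients: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            q = float(fields[1])
            if not 0 <= q <= 1:
                raise ValueError(f"{path}: line {lineno}: quotient {q} outside [0,1]")
            quotients[fields[0]] = q
    return quotients


def read_keyword_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Ordered (substring, broad, specific) functional-category keywords."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            kw, broad, specific = line.split("\t")
            rows.append((kw, broad, specific))
    return rows


def read_external_labels(path: str | Path) -> dict[str, dict]:
    """External classifier labels: scaffold_id, virsorter_category,
    virfinder_score, virfinder_p ('.' or empty for missing values)."""
    labels: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("scaffold_id\t"):
                continue
            sid, cat, score, pval = line.split("\t")
            labels[sid] = {
                "virsorter_category": int(cat) if cat not in (".", "") else None,
                "virfinder_score": float(score) if score not in (".", "") else None,
                "virfinder_p": float(pval) if pval not in (".", "") else None,
            }
    return labels


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# GFF3 gene coordinates

def read_gff3(path: str | Path) -> list[Gene]:
    """Read CDS features from a GFF3 file (1-based inclusive coordinates).

    The ``ID`` attribute names the gene and ``product`` carries the
    functional annotation string.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene = Gene(
                id=attr.get("ID", f"{seqid}_{lineno}"),
                scaffold_id=seqid,
                start=int(start),
                end=int(end),
                strand=strand,
            )
            gene.category_specific = attr.get("product", "unknown")
            genes.append(gene)
    return genes


def write_gff3(genes: list[Gene], path: str | Path,
               products: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            product = (products or {}).get(g.id, g.category_specific)
            attrs = f"ID={g.id};product={product}"
            fh.write(
                f"{g.scaffold_id}\tvirodiv\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# SAM alignments

_CONSUME_BOTH = {0, 7, 8}   # M, =, X
_CONSUME_READ = {1, 4}      # I, S
_CONSUME_REF = {2, 3}       # D, N


def read_sam(path: str | Path, sample_id: str = "", fraction: str = "viral"
             ) -> list[ReadAlignment]:
    """Read a SAM file into ReadAlignment records.

    Unmapped records are skipped; aligned blocks are built from M/=/X cigar
    runs only, so soft-clips and indels never contribute to pileups.
    Reference coordinates are 1-based per SAM convention. A record whose
    reference name is absent from the header is an error (raised by htslib).
    """
    path = Path(path)
    known_refs = set()
    with open(path) as fh:  # htslib silently unmaps unknown RNAMEs; we refuse
        for line in fh:
            if line.startswith("@SQ"):
                for field in line.rstrip("\n").split("\t")[1:]:
                    if field.startswith("SN:"):
                        known_refs.add(field[3:])
            elif not line.startswith("@"):
                fields = line.split("\t")
                if len(fields) > 2 and fields[2] != "*" and fields[2] not in known_refs:
                    raise ValueError(
                        f"{path}: reference {fields[2]!r} absent from header"
                    )
    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            blocks: list[tuple[int, int, int]] = []
            roff = 0
            rpos = rec.reference_start + 1  # to 1-based
            for op, length in rec.cigartuples or []:
                if op in _CONSUME_BOTH:
                    blocks.append((roff, rpos, length))
                    roff += length
                    rpos += length
                elif op in _CONSUME_READ:
                    roff += length
                elif op in _CONSUME_REF:
                    rpos += length
                # H (5) and P (6) consume neither
            if not blocks:
                continue
            score = rec.get_tag("AS") if rec.has_tag("AS") else None
            alignments.append(ReadAlignment(
                read_id=rec.query_name,
                scaffold_id=rec.reference_name,
                blocks=blocks,
                sequence=rec.query_sequence.upper(),
                sample_id=sample_id,
                fraction=fraction,
                score=float(score) if score is not None else None,
            ))
    return alignments


def write_sam(reads: list[tuple[str, str, int, str]],
              references: list[tuple[str, int]], path: str | Path) -> None:
    """Write simple fully-matched single-end records.

    ``reads`` are (name, scaffold_id, pos_1based, sequence) tuples; each is
    emitted with CIGAR ``<len>M``, MAPQ 60 and constant Q40 base qualities.
    Records are sorted by (scaffold, position, name) for byte-stable output.
    """
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in references]
    order = {name: i for i, (name, _) in enumerate(references)}
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for name, sid, pos, seq in sorted(
            reads, key=lambda r: (order[r[1]], r[2], r[0])
        ):
            fh.write(
                f"{name}\t0\t{sid}\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t"
                f"{seq}\t{'I' * len(seq)}\n"
            )
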