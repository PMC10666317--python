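"""Homologous fragments between genomes: plastid-to-mitochondrion transfer.

Plant mitochondrial genomes routinely carry integrated chloroplast DNA
(mitochondrial plastid DNA, MTPT).  This module finds homologous fragments
between two genomes by exact-word seeding and ungapped X-drop extension on
both strands (default thresholds: identity >= 0.70, length >= 30 bp), refines
each fragment with a global edlib alignment to count mismatches and gap
openings, annotates which genes of the donor genome the fragments cover (and
how completely), and summarizes the transferred fraction of the recipient
genome.

Fragment coordinates in reports are 1-based inclusive; a donor-side fragment
on the minus strand is encoded with start > end, the convention of tabular
homology reports.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import edlib

from .core import GeneModel, GenomeRecord, revcomp
from .repeats import _extend_pairs, _self_pairs

__all__ = [
    "HomologFragment",
    "GeneCoverage",
    "TransferSummary",
    "find_homologs",
    "annotate_gene_coverage",
    "transfer_summary",
    "merge_intervals",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class HomologFragment:
    a_start: int  # 1-based inclusive on genome_a
    a_end: int
    b_start: int  # 1-based inclusive on genome_b; start > end means minus strand
    b_end: int
    length: int
    mismatches: int
    gap_openings: int
    identity: float
    evalue_proxy: float
    strand: str

    def a_interval0(self) -> tuple[int, int]:
        return (self.a_start - 1, self.a_end)

    def b_interval0(self) -> tuple[int, int]:
        lo, hi = sorted((self.b_start, self.b_end))
        return (lo - 1, hi)


@dataclass
class GeneCoverage:
    gene: str
    fraction_covered: float  # percentage
    complete: bool


@dataclass
class TransferSummary:
    n_fragments: int
    total_bp: int
    union_bp: int
    fraction_of_genome: float
    fraction_of_genome_union: float
    longest: int
    shortest: int


def _evalue_proxy(score: int, m: int, n: int) -> float:
    # Karlin-Altschul shape with blastn-like constants for +1/-2 scoring;
    # used only for ordering/filter parity, not as a calibrated e-value
    lam, k = 1.28, 0.46
    bits = (lam * score - math.log(k)) / math.log(2)
    return m * n * 2.0 ** (-bits)


def find_homologs(
    genome_a: GenomeRecord | str,
    genome_b: GenomeRecord | str,
    min_identity: float = 0.70,
    min_length: int = 30,
    word: int = 11,
) -> list[HomologFragment]:
    """Homologous fragments of genome_a found in genome_b, both strands.

    Sorted by length descending.  Substitution-level divergence is handled by
    the X-drop extension; each accepted fragment is re-aligned globally with
    edlib to report mismatch and gap-opening counts.
    """
    if isinstance(genome_a, str):
        genome_a = GenomeRecord("a", genome_a)
    if isinstance(genome_b, str):
        genome_b = GenomeRecord("b", genome_b)
    a = genome_a.sequence
    L_b = genome_b.length
    out: list[HomologFragment] = []
    seen: set[tuple] = set()
    for strand, b in (("+", genome_b.sequence), ("-", revcomp(genome_b.sequence))):
        pairs = _self_pairs(a, b, word, same=False)
        for qs, qe, ts, te, ident in _extend_pairs(a, b, pairs, word,
                                                   min_length, min_identity):
            length = qe - qs
            a_sub, b_sub = a[qs:qe], b[ts:te]
            aln = edlib.align(a_sub, b_sub, mode="NW", task="path")
            mism, gaps = _cigar_stats(aln["cigar"])
            score = (length - mism) - 2 * mism - 5 * gaps
            if strand == "+":
                b_start, b_end = ts + 1, te
            else:
                b_start, b_end = L_b - ts, L_b - te + 1  # start > end: minus strand
            key = (qs, qe, b_start, b_end)
            if key in seen:
                continue
            seen.add(key)
            out.append(HomologFragment(
                a_start=qs + 1, a_end=qe,
                b_start=b_start, b_end=b_end,
                length=length,
                mismatches=mism,
                gap_openings=gaps,
                identity=round(ident, 4),
                evalue_proxy=_evalue_proxy(score, len(a), L_b),
                strand=strand,
            ))
    out.sort(key=lambda f: (-f.length, f.a_start))
    return out


def _cigar_stats(cigar: str) -> tuple[int, int]:
    mism = 0
    gap_open = 0
    prev_gap = False
    for num, op in _CIGAR_RE.findall(cigar or ""):
        n = int(num)
        if op == "X":
            mism += n
            prev_gap = False
        elif op in "ID":
            if not prev_gap:
                gap_open += 1
            prev_gap = True
        else:
            prev_gap = False
    return mism, gap_open


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def annotate_gene_coverage(
    fragments: list[HomologFragment],
    genes_on_b: list[GeneModel],
) -> list[GeneCoverage]:
    """How completely each donor-genome gene is covered by the fragments.

    Fragment intervals on genome_b are merged first, so overlapping fragments
    (e.g. the two inverted-repeat copies of a plastid region) do not double
    count.  Genes with no overlap are omitted.
    """
    merged = merge_intervals([f.b_interval0() for f in fragments])
    out: list[GeneCoverage] = []
    for gene in genes_on_b:
        glen = gene.span_length()
        if glen == 0:
            continue
        covered = 0
        for gs, ge in gene.exons:
            for ms, me in merged:
                covered += max(0, min(ge, me) - max(gs, ms))
        if covered == 0:
            continue
        frac = round(100.0 * covered / glen, 2)
        out.append(GeneCoverage(gene=gene.name, fraction_covered=min(frac, 100.0),
                                complete=covered >= glen))
    return out


def transfer_summary(
    fragments: list[HomologFragment],
    genome_a_length: int,
) -> TransferSummary:
    """Fragment totals and the transferred fraction of the recipient genome.

    ``fraction_of_genome`` uses the plain sum of fragment lengths (the
    convention of printed homology tables); the union-based alternative is
    reported alongside.
    """
    if genome_a_length <= 0:
        raise ValueError("genome length must be positive")
    if not fragments:
        return TransferSummary(0, 0, 0, 0.0, 0.0, 0, 0)
    lengths = [f.length for f in fragments]
    total = sum(lengths)
    union = sum(e - s for s, e in merge_intervals([f.a_interval0() for f in fragments]))
    return TransferSummary(
        n_fragments=len(fragments),
        total_bp=total,
        union_bp=union,
        fraction_of_genome=round(100.0 * total / genome_a_length, 2),
        fraction_of_genome_union=round(100.0 * union / genome_a_length, 2),
        longest=max(lengths),
        shortest=min(lengths),
    )
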