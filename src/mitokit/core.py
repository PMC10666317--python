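"""Domain types, FASTA/annotation I/O and circular-coordinate arithmetic.

Plant mitochondrial genomes are typically circular molecules of a few hundred
kilobases.  Everything downstream (repeat mining, read recruitment, transfer
detection) works on :class:`GenomeRecord` objects whose position arithmetic is
modulo the genome length when ``circular`` is set.  Internally all intervals
are 0-based half-open; user-facing report tables are 1-based inclusive, the
convention of GenBank-style gene tables.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "GeneModel",
    "GenomeStats",
    "FastaFormatError",
    "CoordinateError",
    "FrameError",
    "read_fasta",
    "write_fasta",
    "genome_stats",
    "extract_cds",
    "protein_length",
    "translate_cds",
    "revcomp",
    "read_gene_table",
    "write_gene_table",
    "read_gff3_genes",
]

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for empty files or non-IUPAC characters in sequence input."""


class CoordinateError(ValueError):
    """Raised when an interval falls outside a (linearised) genome."""


class FrameError(ValueError):
    """Raised when a CDS length is not a multiple of three."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A genome (or contig) sequence with circularity metadata."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FastaFormatError(
                f"record {self.id!r}: non-IUPAC character {self.sequence[pos]!r} "
                f"at sequence position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end) with modulo-length wrap on circular genomes.

        ``end`` may exceed the genome length on a circular genome, in which
        case the slice continues from the origin.
        """
        n = self.length
        if start < 0 or start > n:
            raise CoordinateError(f"start {start} outside genome of length {n}")
        if end < start:
            raise CoordinateError(f"empty/negative interval [{start}, {end})")
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise CoordinateError(
                f"interval [{start}, {end}) beyond linear genome of length {n}"
            )
        if end - start > n:
            raise CoordinateError("interval longer than circular genome")
        return self.sequence[start:] + self.sequence[: end - n]

    def rotated(self, offset: int) -> "GenomeRecord":
        """Same circular molecule with the origin moved to ``offset``."""
        n = self.length
        offset %= n
        return GenomeRecord(self.id, self.sequence[offset:] + self.sequence[:offset], self.circular)


@dataclass
class GeneModel:
    """A gene annotation: exons on the genome, strand, codons, copy metadata.

    ``exons`` are 0-based half-open intervals in genome order along the plus
    strand; an exon of a circular gene may run past the genome end (wrap).
    Pseudogenes carry no coding contract and are skipped by CDS operations.
    """

    name: str
    category: str
    strand: str
    exons: list[tuple[int, int]]
    start_codon: str = "ATG"
    stop_codon: str = ""
    copy_number: int = 1
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be + or -")

    @property
    def intron_count(self) -> int:
        return max(len(self.exons) - 1, 0)

    def span_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeStats:
    length: int
    gc_percent: float | None
    gene_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (uppercased, order preserved)."""
    path = Path(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeRecord(rec.id, str(rec.seq), circular=circular))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Statistics

def genome_stats(genome: GenomeRecord, genes: Sequence[GeneModel] = ()) -> GenomeStats:
    """Genome length, GC% (Ns excluded from the denominator) and gene census."""
    seq = genome.sequence
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        gc: float | None = None
    else:
        gc = 100.0 * (seq.count("G") + seq.count("C")) / acgt
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.category] = counts.get(g.category, 0) + g.copy_number
    return GenomeStats(length=genome.length, gc_percent=gc, gene_counts=counts)


# ---------------------------------------------------------------------------
# CDS extraction / translation

def extract_cds(genome: GenomeRecord, gene: GeneModel) -> str:
    """Concatenated exon sequence 5'->3' (minus strand reverse-complemented).

    Exons of circular genes may cross the origin (interval end beyond the
    genome length).  Pseudogenes are skipped with a warning and return "".
    """
    if gene.pseudo:
        warnings.warn(f"gene {gene.name} is a pseudogene; no CDS extracted")
        return ""
    parts = [genome.fetch(s, e) for s, e in gene.exons]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = revcomp(cds)
    return cds


def protein_length(cds: str) -> int:
    """Number of encoded amino acids.

    The terminal stop codon is not counted; if the CDS does not end in a stop
    (gene tables often print coding length without the stop), every codon
    counts.  Internal stops raise a warning with their codon position.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    for i in range(n_codons - 1):
        codon = cds[3 * i : 3 * i + 3]
        if codon in ("TAA", "TAG", "TGA"):
            warnings.warn(f"internal stop codon {codon} at codon {i + 1}")
    if cds[-3:] in ("TAA", "TAG", "TGA"):
        return n_codons - 1
    return n_codons


def translate_cds(cds: str, to_stop: bool = False) -> str:
    """Standard-genetic-code translation; codons containing N give X."""
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate(table=1, to_stop=to_stop)).replace("*", "X" if not to_stop else "")


# ---------------------------------------------------------------------------
# Gene tables (TSV dialect) and GFF3

_TABLE_COLUMNS = [
    "name", "category", "strand", "exons",
    "start_codon", "stop_codon", "copies", "pseudo",
]


def _format_exons(exons: list[tuple[int, int]]) -> str:
    # user-facing 1-based inclusive
    return ";".join(f"{s + 1}-{e}" for s, e in exons)


def _parse_exons(text: str) -> list[tuple[int, int]]:
    out = []
    for part in text.split(";"):
        a, b = part.split("-")
        out.append((int(a) - 1, int(b)))
    return out


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TABLE_COLUMNS)
        for g in genes:
            w.writerow([
                g.name, g.category, g.strand, _format_exons(g.exons),
                g.start_codon, g.stop_codon, g.copy_number, int(g.pseudo),
            ])


def read_gene_table(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genes.append(GeneModel(
                name=row["name"],
                category=row["category"],
                strand=row["strand"],
                exons=_parse_exons(row["exons"]),
                start_codon=row.get("start_codon", "ATG"),
                stop_codon=row.get("stop_codon", ""),
                copy_number=int(row.get("copies", 1)),
                pseudo=bool(int(row.get("pseudo", 0))),
            ))
    return genes


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene + CDS/exon features, grouped by Parent)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for gene in db.features_of_type("gene"):
        exons = []
        for child in db.children(gene, featuretype=("CDS", "exon"), order_by="start"):
            exons.append((child.start - 1, child.end))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        # CDS rows shadow exon rows when both present
        cds = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS", order_by="start")]
        if cds:
            exons = cds
        genes.append(GeneModel(
            name=gene.attributes.get("Name", [gene.id])[0],
            category=gene.attributes.get("gene_biotype", ["protein_coding"])[0],
            strand=gene.strand if gene.strand in "+-" else "+",
            exons=sorted(set(exons)),
        ))
    return genes
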