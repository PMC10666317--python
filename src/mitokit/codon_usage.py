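"""Codon counting and relative synonymous codon usage (RSCU).

RSCU of a codon c in synonym family f of size k is

    RSCU_c = n_c * k / sum_{c' in f} n_{c'}

i.e. the observed count over the count expected if all synonyms of the family
were used equally.  Values above 1 mark preferred codons; within any family
with nonzero usage the values average to exactly 1.

Counting follows the "unique CDS" convention: a multi-copy gene contributes
its coding sequence once (deduplication by exact sequence), and the terminal
stop codon is excluded.  Synonym families default to the standard genetic
code, with methionine (ATG) and tryptophan (TGG) as singleton families and
stop codons excluded.  An optional start-codon grouping treats ATG/CTG/TTG as
one three-codon "Met" family (moving CTG and TTG out of the leucine family),
a convention some organelle codon-usage reports use.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

from .core import FrameError, translate_cds

__all__ = [
    "CodonCounts",
    "RSCUTable",
    "ALL_CODONS",
    "count_codons",
    "rscu",
    "at_ending_census",
    "write_rscu_tsv",
]

ALL_CODONS = ["".join(p) for p in product("TCAG", repeat=3)]
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: codon -> amino acid (one letter, stops as X) under the standard code
CODON_AA = {c: translate_cds(c) for c in ALL_CODONS}


@dataclass
class CodonCounts:
    counts: dict[str, int]
    n_cds: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RSCUTable:
    rscu: dict[str, float | None]
    family: dict[str, str]
    family_size: dict[str, int]
    counts: dict[str, int] = field(default_factory=dict)


def count_codons(
    cds_list: list[str],
    dedupe: bool = True,
    exclude_terminal_stop: bool = True,
) -> CodonCounts:
    """Count in-frame codons across a CDS set (unique sequences by default)."""
    counts = {c: 0 for c in ALL_CODONS}
    seen: set[str] = set()
    n_used = 0
    for cds in cds_list:
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise FrameError(f"CDS length {len(cds)} not divisible by 3")
        if dedupe:
            if cds in seen:
                continue
            seen.add(cds)
        n_used += 1
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if exclude_terminal_stop and codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for codon in codons:
            if codon in counts:  # codons containing N are skipped
                counts[codon] += 1
    return CodonCounts(counts=counts, n_cds=n_used)


def _families(met_family: tuple[str, ...] | None, include_stops: bool) -> dict[str, str]:
    """codon -> family id (family id is the amino acid, or 'Met*' group)."""
    fam: dict[str, str] = {}
    for codon in ALL_CODONS:
        aa = CODON_AA[codon]
        if aa == "X" and not include_stops:
            continue
        fam[codon] = aa
    if met_family:
        for codon in met_family:
            codon = codon.upper().replace("U", "T")
            fam[codon] = "M"
    return fam


def rscu(
    counts: CodonCounts,
    met_family: tuple[str, ...] | None = None,
    include_stops: bool = False,
) -> RSCUTable:
    """RSCU_c = n_c * k / sum over the codon's synonym family.

    Families whose total count is zero get RSCU ``None`` (missing) for every
    member.
    """
    fam = _families(met_family, include_stops)
    members: dict[str, list[str]] = {}
    for codon, f in fam.items():
        members.setdefault(f, []).append(codon)
    values: dict[str, float | None] = {}
    family_size = {f: len(m) for f, m in members.items()}
    for f, codons in members.items():
        total = sum(counts.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            values[c] = None if total == 0 else counts.counts.get(c, 0) * k / total
    return RSCUTable(rscu=values, family=fam, family_size=family_size,
                     counts=dict(counts.counts))


def at_ending_census(table: RSCUTable) -> tuple[int, int, float | None]:
    """Census of preferred codons: (RSCU>1 count, of which A/T-ending, %)."""
    gt1 = [c for c, v in table.rscu.items() if v is not None and v > 1.0]
    at = [c for c in gt1 if c[2] in "AT"]
    if not gt1:
        return (0, 0, None)
    return (len(gt1), len(at), round(100.0 * len(at) / len(gt1), 2))


def write_rscu_tsv(table: RSCUTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["codon", "amino_acid", "count", "RSCU"])
        for codon in sorted(table.rscu):
            v = table.rscu[codon]
            w.writerow([codon, CODON_AA[codon], table.counts.get(codon, 0),
                        "" if v is None else f"{v:.4f}"])
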