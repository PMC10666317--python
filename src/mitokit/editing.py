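"""C-to-U RNA editing effects on mitochondrial coding sequences.

Plant mitochondrial mRNAs are post-transcriptionally edited almost exclusively
by cytidine-to-uridine conversion, which reads as C->T at the cDNA level.
Given a list of edit sites on a CDS this module applies them, classifies each
codon change by the hydropathy transition of the encoded residue (the
five-class scheme: hydrophilic->hydrophilic, hydrophilic->hydrophobic,
hydrophilic->stop, hydrophobic->hydrophilic, hydrophobic->hydrophobic) and
summarizes a whole edit-site census: per-class percentages, codon-position
distribution, target amino-acid spectrum, stop gains and start-codon creation.

Site *prediction* is out of scope — sites arrive as inputs (gene, CDS
position), as produced by organelle editing predictors.

The residue hydropathy classes used here::

    hydrophobic:  A V L I P F M W
    hydrophilic:  R N D C Q E H K S T Y G
    stop:         its own class

C (cysteine) and T (threonine) sit in the hydrophilic class, and a stop gain
is always its own category regardless of the source residue.  G (glycine) is
assigned hydrophilic by the sign of its Kyte-Doolittle index; it can be moved
with ``set_glycine_class``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .core import GeneModel, translate_cds

__all__ = [
    "EditSite",
    "CodonChange",
    "EditingSummary",
    "HYDROPHOBIC",
    "HYDROPHILIC",
    "hydropathy_class",
    "apply_edits",
    "classify_change",
    "summarize_edits",
    "detect_functional_effects",
    "load_observed_edit_counts",
    "read_sites_tsv",
]

HYDROPHOBIC = set("AVLIPFMW")
HYDROPHILIC = set("RNDCQEHKSTYG")

STOPS = {"TAA", "TAG", "TGA"}


class EditValidationError(ValueError):
    """An edit site whose reference base is not C, or a non-C->T change."""


def set_glycine_class(hydrophobic: bool) -> None:
    """Reassign glycine's hydropathy class (default hydrophilic)."""
    if hydrophobic:
        HYDROPHILIC.discard("G")
        HYDROPHOBIC.add("G")
    else:
        HYDROPHOBIC.discard("G")
        HYDROPHILIC.add("G")


def hydropathy_class(aa: str) -> str:
    if aa == "X" or aa == "*":
        return "stop"
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    if aa in HYDROPHILIC:
        return "hydrophilic"
    raise ValueError(f"unknown amino acid {aa!r}")


@dataclass(frozen=True)
class EditSite:
    """A C->U edit at a 1-based position of a CDS."""

    gene: str
    cds_position: int

    @property
    def codon_index(self) -> int:
        return (self.cds_position + 2) // 3

    @property
    def codon_position(self) -> int:
        return (self.cds_position - 1) % 3 + 1


@dataclass(frozen=True)
class CodonChange:
    from_codon: str
    to_codon: str
    from_aa: str
    to_aa: str
    positions_edited: frozenset[int]
    category: str


@dataclass
class EditingSummary:
    total_sites: int
    per_category: dict[str, tuple[int, float]]
    per_codon_position: dict[str, int]  # pos1, pos2, pos3, both12 ...
    per_target_aa: dict[str, float]
    unchanged_percent: float | None = None
    premature_stops: list[str] = field(default_factory=list)
    start_creations: list[str] = field(default_factory=list)


def apply_edits(cds: str, sites: list[EditSite]) -> str:
    """Apply C->T edits; every site's reference base must be C."""
    cds = cds.upper()
    seq = list(cds)
    bad = [s for s in sites if s.cds_position < 1 or s.cds_position > len(cds)
           or cds[s.cds_position - 1] != "C"]
    if bad:
        detail = "; ".join(f"{s.gene}:{s.cds_position}" for s in bad)
        raise EditValidationError(f"sites whose reference base is not C: {detail}")
    for s in sites:
        seq[s.cds_position - 1] = "T"
    return "".join(seq)


def classify_change(from_codon: str, to_codon: str) -> CodonChange:
    """Classify a codon change produced by C->T edits.

    The two codons may differ at any subset of positions, but every
    difference must be a C in the source and a T in the edited codon.
    """
    from_codon = from_codon.upper()
    to_codon = to_codon.upper()
    if len(from_codon) != 3 or len(to_codon) != 3:
        raise ValueError("codons must be 3 bases")
    diffs = [i for i in range(3) if from_codon[i] != to_codon[i]]
    if not diffs:
        raise EditValidationError("codons are identical; no edit to classify")
    for i in diffs:
        if not (from_codon[i] == "C" and to_codon[i] == "T"):
            raise EditValidationError(
                f"{from_codon}->{to_codon}: position {i + 1} is not a C->T change")
    from_aa = translate_cds(from_codon)
    to_aa = translate_cds(to_codon)
    category = f"{hydropathy_class(from_aa)}-{hydropathy_class(to_aa)}"
    return CodonChange(
        from_codon=from_codon,
        to_codon=to_codon,
        from_aa=from_aa,
        to_aa=to_aa,
        positions_edited=frozenset(i + 1 for i in diffs),
        category=category,
    )


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 2)


def summarize_edits(changes: list[tuple[CodonChange, int]]) -> EditingSummary:
    """Aggregate (codon change, count) pairs into a census summary."""
    total = sum(c for _, c in changes)
    if total == 0:
        return EditingSummary(0, {}, {}, {}, None)
    cat_counts: dict[str, int] = {}
    pos_counts = {"pos1": 0, "pos2": 0, "pos3": 0, "both12": 0, "other_multi": 0}
    aa_counts: dict[str, int] = {}
    for change, n in changes:
        cat_counts[change.category] = cat_counts.get(change.category, 0) + n
        pe = change.positions_edited
        if pe == {1}:
            pos_counts["pos1"] += n
        elif pe == {2}:
            pos_counts["pos2"] += n
        elif pe == {3}:
            pos_counts["pos3"] += n
        elif pe == {1, 2}:
            pos_counts["both12"] += n
        else:
            pos_counts["other_multi"] += n
        aa_counts[change.to_aa] = aa_counts.get(change.to_aa, 0) + n
    per_category = {cat: (n, _pct(n, total)) for cat, n in sorted(cat_counts.items())}
    unchanged = (cat_counts.get("hydrophilic-hydrophilic", 0)
                 + cat_counts.get("hydrophobic-hydrophobic", 0))
    return EditingSummary(
        total_sites=total,
        per_category=per_category,
        per_codon_position=pos_counts,
        per_target_aa={aa: _pct(n, total) for aa, n in sorted(aa_counts.items())},
        unchanged_percent=_pct(unchanged, total),
    )


def changes_from_sites(cds: str, sites: list[EditSite]) -> list[tuple[CodonChange, int]]:
    """Group edit sites by codon into codon changes (dual edits count once)."""
    cds = cds.upper()
    by_codon: dict[int, list[EditSite]] = {}
    for s in sites:
        by_codon.setdefault(s.codon_index, []).append(s)
    out = []
    for ci in sorted(by_codon):
        from_codon = cds[3 * (ci - 1) : 3 * ci]
        if len(from_codon) != 3:
            raise EditValidationError(f"site beyond CDS end in codon {ci}")
        to_codon = list(from_codon)
        for s in by_codon[ci]:
            if from_codon[s.codon_position - 1] != "C":
                raise EditValidationError(
                    f"{s.gene}:{s.cds_position}: reference base is not C")
            to_codon[s.codon_position - 1] = "T"
        out.append((classify_change(from_codon, "".join(to_codon)), 1))
    return out


def detect_functional_effects(
    gene: GeneModel | str,
    cds: str,
    sites: list[EditSite],
) -> tuple[bool, int | None, bool]:
    """Stop gains and start-codon creation caused by editing.

    Returns (premature_stop, first_stop_codon_index_or_None, start_created).
    A premature stop is an edited codon becoming TAA/TAG/TGA before the
    terminal codon; a created start is codon 1 ACG edited to ATG.
    """
    name = gene.name if isinstance(gene, GeneModel) else str(gene)
    del name
    edited = apply_edits(cds, sites)
    n_codons = len(edited) // 3
    premature, first_pos = False, None
    for i in range(n_codons - 1):
        before = cds.upper()[3 * i : 3 * i + 3]
        after = edited[3 * i : 3 * i + 3]
        if after in STOPS and before not in STOPS:
            premature, first_pos = True, i + 1
            break
    start_created = cds.upper()[:3] == "ACG" and edited[:3] == "ATG"
    return premature, first_pos, start_created


# ---------------------------------------------------------------------------
# I/O


def load_observed_edit_counts() -> list[tuple[CodonChange, int]]:
    """The bundled C->U edit-type census of the Forsythia suspensa
    mitochondrial genome (codon change, observed count)."""
    ref = resources.files("mitokit.data").joinpath("forsythia_mt_edit_types.tsv")
    out = []
    with ref.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append((classify_change(row["from_codon"], row["to_codon"]),
                        int(row["count"])))
    return out


def read_sites_tsv(path: str | Path) -> list[EditSite]:
    """Edit-site TSV with columns gene, cds_position."""
    sites = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sites.append(EditSite(gene=row["gene"], cds_position=int(row["cds_position"])))
    return sites


def write_summary_tsv(summary: EditingSummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["metric", "value"])
        w.writerow(["total_sites", summary.total_sites])
        for cat, (n, pct) in summary.per_category.items():
            w.writerow([f"count[{cat}]", n])
            w.writerow([f"percent[{cat}]", pct])
        for key, n in summary.per_codon_position.items():
            w.writerow([f"sites_{key}", n])
        for aa, pct in summary.per_target_aa.items():
            w.writerow([f"percent_target[{aa}]", pct])
        w.writerow(["unchanged_percent", summary.unchanged_percent])
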