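"""Pairwise Ka/Ks (NG86 and modified LWL) and nucleotide diversity Pi.

Selection on protein-coding genes is read from the ratio of nonsynonymous to
synonymous substitution rates, omega = Ka/Ks: omega > 1 positive selection,
omega < 1 purifying selection, omega = 1 neutral evolution.

Two estimators are provided:

* **NG86** (Nei & Gojobori 1986): synonymous/nonsynonymous site counting per
  codon, pathway-averaged difference counting for multi-hit codons (pathways
  through stop codons excluded when an alternative exists), and Jukes-Cantor
  multiple-hit correction.  Undefined corrections (p >= 3/4, or Ks = 0 for the
  ratio) are reported as missing, never as infinities.
* **MLWL** (modified Li-Wu-Luo): positions are partitioned by codon degeneracy
  (nondegenerate, two-fold, four-fold), transitions and transversions are
  counted per class, each class gets a Kimura two-parameter correction, and
  the two-fold sites are apportioned between synonymous and nonsynonymous
  using the transition/transversion rate ratio kappa estimated from the
  four-fold-site K2P components (kappa = 2*A4/B4; kappa = 1 recovers the
  original LWL85 weighting of 1/3 : 2/3).

Pi is the mean pairwise difference per site across an alignment of >= 2
sequences, with complete deletion of gap-containing columns.

Sequences must arrive aligned (codon-aware); `strip_gap_codons` removes codon
columns containing gaps from a pairwise codon alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .core import translate_cds

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "PiResult",
    "ng86",
    "mlwl",
    "pi",
    "classify_selection",
    "strip_gap_codons",
]

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_AA = {}


def _aa(codon: str) -> str:
    if codon not in _AA:
        _AA[codon] = translate_cds(codon)
    return _AA[codon]


@dataclass
class CodonAlignment:
    """Aligned coding sequences (pairwise or multiple), possibly with gaps."""

    seqs: list[str]
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if self.ids is None:
            self.ids = [f"seq{i + 1}" for i in range(len(self.seqs))]

    @property
    def length(self) -> int:
        return len(self.seqs[0])


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    method: str
    sites_n: float
    sites_s: float


@dataclass
class PiResult:
    gene: str
    pi: float
    n_sequences: int
    sites_used: int


def strip_gap_codons(a: str, b: str) -> tuple[str, str]:
    """Drop codon columns where either sequence has a gap or N (pairwise)."""
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    n = len(a) - len(a) % 3
    out_a, out_b = [], []
    for i in range(0, n, 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca + cb) <= set(BASES):
            out_a.append(ca)
            out_b.append(cb)
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# NG86


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon (sums to 3)."""
    syn = 0.0
    aa0 = _aa(codon)
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if _aa(mutant) == aa0 and mutant not in STOPS:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of a codon pair."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS and nxt != c2:
                blocked = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, bl in paths if not bl]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p < 0 or p >= 0.75:
        return None
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return d if d > 0 else 0.0


def _codon_pairs(aln: CodonAlignment) -> list[tuple[str, str]]:
    if len(aln.seqs) != 2:
        raise ValueError("pairwise alignment required")
    a, b = strip_gap_codons(aln.seqs[0], aln.seqs[1])
    pairs = [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]
    # drop terminal stop codons
    while pairs and (pairs[-1][0] in STOPS or pairs[-1][1] in STOPS):
        pairs.pop()
    if not pairs:
        raise ValueError("no codons left after gap/stop filtering")
    return pairs


def ng86(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction."""
    pairs = _codon_pairs(aln)
    s_a = s_b = 0.0
    sd = nd = 0.0
    for c1, c2 in pairs:
        sa, _ = _codon_sites(c1)
        sb, _ = _codon_sites(c2)
        s_a += sa
        s_b += sb
        d_s, d_n = _pathway_diffs(c1, c2)
        sd += d_s
        nd += d_n
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(pairs) - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, method="NG86", sites_n=N, sites_s=S)


# ---------------------------------------------------------------------------
# LWL85 / MLWL


def _degeneracy(codon: str, pos: int) -> int:
    """0 (nondegenerate), 2 (two-fold) or 4 (four-fold) class of a position."""
    aa0 = _aa(codon)
    n_syn = 0
    for alt in BASES:
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1 :]
        if _aa(mutant) == aa0:
            n_syn += 1
    if n_syn == 0:
        return 0
    if n_syn == 3:
        return 4
    return 2


def _k2p(P: float, Q: float) -> tuple[float, float] | None:
    """Kimura 2-parameter (A, B) components; None when saturated."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return None
    A = 0.5 * math.log(1.0 / w1) - 0.25 * math.log(1.0 / w2)
    B = 0.5 * math.log(1.0 / w2)
    return A, B


def _lwl_counts(pairs: list[tuple[str, str]]):
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    S = {0: 0.0, 2: 0.0, 4: 0.0}  # transitions per class
    V = {0: 0.0, 2: 0.0, 4: 0.0}  # transversions per class
    for c1, c2 in pairs:
        for pos in range(3):
            d1 = _degeneracy(c1, pos)
            d2 = _degeneracy(c2, pos)
            L[d1] += 0.5
            L[d2] += 0.5
            if c1[pos] != c2[pos]:
                kind = S if (c1[pos], c2[pos]) in TRANSITIONS else V
                kind[d1] += 0.5
                kind[d2] += 0.5
    return L, S, V


def mlwl(aln: CodonAlignment, kappa: float | None = None) -> KaKsResult:
    """Modified LWL Ka/Ks: K2P per degeneracy class, kappa-weighted 2-fold sites.

    ``kappa`` (transition/transversion rate ratio) defaults to the estimate
    2*A4/B4 from the four-fold-site K2P components, clamped to >= 0.1; pass
    ``kappa=1`` to reproduce the classical LWL85 1/3 : 2/3 apportioning.
    """
    pairs = _codon_pairs(aln)
    L, Scnt, Vcnt = _lwl_counts(pairs)
    AB = {}
    for cls in (0, 2, 4):
        if L[cls] == 0:
            AB[cls] = (0.0, 0.0)
            continue
        res = _k2p(Scnt[cls] / L[cls], Vcnt[cls] / L[cls])
        if res is None:
            return KaKsResult(ka=None, ks=None, ratio=None, method="MLWL",
                              sites_n=L[0] + 2 * L[2] / 3, sites_s=L[2] / 3 + L[4])
        AB[cls] = res
    A0, B0 = AB[0]
    A2, B2 = AB[2]
    A4, B4 = AB[4]
    if kappa is None:
        kappa = 2.0 * A4 / B4 if B4 > 0 else 1.0
        kappa = max(kappa, 0.1)
    syn2 = kappa / (kappa + 2.0)  # synonymous share of a two-fold site
    S_sites = L[2] * syn2 + L[4]
    N_sites = L[0] + L[2] * (1.0 - syn2)
    ks = (L[2] * A2 + L[4] * (A4 + B4)) / S_sites if S_sites > 0 else None
    ka = (L[2] * B2 + L[0] * (A0 + B0)) / N_sites if N_sites > 0 else None
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, method="MLWL",
                      sites_n=N_sites, sites_s=S_sites)


# ---------------------------------------------------------------------------
# Nucleotide diversity


def pi(aln: CodonAlignment, gene: str = "", pairwise_deletion: bool = False) -> PiResult:
    """Average pairwise differences per site (complete deletion by default)."""
    if len(aln.seqs) < 2:
        raise ValueError("pi requires at least 2 sequences")
    mat = np.frombuffer("".join(aln.seqs).encode(), dtype=np.uint8)
    mat = mat.reshape(len(aln.seqs), aln.length)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(aln.seqs)
    n_pairs = n * (n - 1) // 2
    if pairwise_deletion:
        total = 0.0
        used_min = aln.length
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                sites = int(both.sum())
                if sites == 0:
                    continue
                diffs = int(((mat[i] != mat[j]) & both).sum())
                total += diffs / sites
                used_min = min(used_min, sites)
        return PiResult(gene=gene, pi=total / n_pairs, n_sequences=n, sites_used=used_min)
    keep = valid.all(axis=0)
    sites = int(keep.sum())
    if sites == 0:
        return PiResult(gene=gene, pi=0.0, n_sequences=n, sites_used=0)
    sub = mat[:, keep]
    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int((sub[i] != sub[j]).sum())
    return PiResult(gene=gene, pi=diffs / (n_pairs * sites), n_sequences=n,
                    sites_used=sites)


def classify_selection(result: KaKsResult, tol: float = 1e-9) -> str:
    """positive / purifying / neutral / undetermined from the Ka/Ks ratio."""
    r = result.ratio
    if r is None:
        return "undetermined"
    if abs(r - 1.0) <= tol:
        return "neutral"
    return "positive" if r > 1.0 else "purifying"
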