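"""Iterative seed-based recruitment ("baiting") of organelle long reads.

Assembling a plant mitochondrial genome from whole-genome long reads starts by
pulling the mitochondrial fraction out of a pool dominated by nuclear and
plastid reads.  The procedure implemented here:

1. reads sharing an alignment block longer than 50 bp with any conserved
   mitochondrial core gene become *candidates*;
2. candidates covering more distinct core genes, more completely, are ranked
   and the top ones become *seeds*;
3. every remaining read that overlaps a recruited read by at least 1 kb at
   70% or better identity is added, and the step repeats until a round adds
   nothing.

Overlap detection is a self-contained minimizer chainer: shared (k, w)
minimizers are clustered by diagonal, the best clusters are extended either to
the chain bounds (gene scanning) or to a full dovetail overlap (read-vs-read
recruitment), and identity over the block is computed by global edlib
alignment.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .core import GenomeRecord, revcomp

__all__ = [
    "LongRead",
    "AlignmentHit",
    "RecruitmentResult",
    "CoreGeneIndex",
    "minimizers",
    "overlap_detect",
    "scan_candidates",
    "score_seed",
    "select_seeds",
    "recruit_iterative",
]

DEFAULT_K = 15
DEFAULT_W = 10
SCAN_K = 11
SCAN_W = 5
MIN_SHARED = 3  # minimizer matches needed before a diagonal cluster is chained

_BASE_CODE = np.full(256, 4, dtype=np.int64)  # N and anything else -> 4
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_MIX = np.int64(0x2545F4914F6CDD1D)


@dataclass
class LongRead:
    id: str
    sequence: str
    truth_label: str | None = None  # {mito, plastid, nuclear}; synthetic only

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        self.sequence = self.sequence.upper()


@dataclass
class AlignmentHit:
    query_id: str
    target_id: str
    q_interval: tuple[int, int]
    t_interval: tuple[int, int]
    block_length: int
    identity: float
    orientation: str  # '+' or '-'


@dataclass
class RecruitmentResult:
    seed_ids: set[str]
    recruited_ids: list[str]
    rounds: int
    per_round_added: list[int]
    report: list[dict] = field(default_factory=list)


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Base-5 integer code of every k-mer (A,C,G,T,N -> 0..4)."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    powers = np.power(np.int64(5), np.arange(k - 1, -1, -1, dtype=np.int64))
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    return windows @ powers


def minimizers(seq: str, k: int = DEFAULT_K, w: int = DEFAULT_W) -> list[tuple[int, int]]:
    """(w, k)-minimizers of ``seq`` as (kmer code, position), deduplicated."""
    codes = _kmer_codes(seq, k)
    m = len(codes)
    if m == 0:
        return []
    hashes = (codes * _MIX) & np.int64(0x7FFFFFFFFFFFFFFF)
    if m <= w:
        pos = int(hashes.argmin())
        return [(int(codes[pos]), pos)]
    win = np.lib.stride_tricks.sliding_window_view(hashes, w)
    picks = win.argmin(axis=1) + np.arange(m - w + 1)
    picks = np.unique(picks)
    return [(int(codes[p]), int(p)) for p in picks]


def _diagonal_clusters(matches: list[tuple[int, int]], band: int = 200) -> list[list[tuple[int, int]]]:
    """Group (q_pos, t_pos) matches into diagonal bands, merging adjacent bands."""
    by_band: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for qp, tp in matches:
        by_band[(qp - tp) // band].append((qp, tp))
    clusters: list[list[tuple[int, int]]] = []
    used: set[int] = set()
    for b in sorted(by_band):
        if b in used:
            continue
        cluster = list(by_band[b])
        nb = b + 1
        while nb in by_band:
            used.add(nb)
            cluster.extend(by_band[nb])
            nb += 1
        clusters.append(sorted(cluster))
    return clusters


def _greedy_extend(a: str, b: str, qs: int, qe: int, ts: int, te: int) -> tuple[int, int, int, int]:
    """Extend chain bounds base-by-base while the sequences keep matching."""
    while qs > 0 and ts > 0 and a[qs - 1] == b[ts - 1]:
        qs -= 1
        ts -= 1
    la, lb = len(a), len(b)
    while qe < la and te < lb and a[qe] == b[te]:
        qe += 1
        te += 1
    return qs, qe, ts, te


def _identity(a_block: str, b_block: str) -> float:
    if not a_block or not b_block:
        return 0.0
    span = max(len(a_block), len(b_block))
    dist = edlib.align(a_block, b_block, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / span


def _hits_one_orientation(
    a: str,
    b: str,
    b_index: dict[int, list[int]],
    a_mins: list[tuple[int, int]],
    k: int,
    mode: str,
) -> list[tuple[int, int, int, int, float]]:
    matches: list[tuple[int, int]] = []
    for code, qp in a_mins:
        for tp in b_index.get(code, ()):
            matches.append((qp, tp))
    if len(matches) < MIN_SHARED:
        return []
    hits = []
    for cluster in _diagonal_clusters(matches):
        if len(cluster) < MIN_SHARED:
            continue
        qs = min(q for q, _ in cluster)
        qe = max(q for q, _ in cluster) + k
        ts = min(t for _, t in cluster)
        te = max(t for _, t in cluster) + k
        if mode == "dovetail":
            # extend along the median diagonal to the sequence ends: the
            # contract is a read-vs-read overlap, so the block runs end-to-end
            diag = sorted(q - t for q, t in cluster)[len(cluster) // 2]
            qs = max(0, diag)
            qe = min(len(a), len(b) + diag)
            ts = max(0, -diag)
            te = min(len(b), len(a) - diag)
        else:
            qs, qe, ts, te = _greedy_extend(a, b, qs, qe, ts, te)
        ident = _identity(a[qs:qe], b[ts:te])
        hits.append((qs, qe, ts, te, ident))
    return hits


def _build_index(mins: list[tuple[int, int]]) -> dict[int, list[int]]:
    idx: dict[int, list[int]] = defaultdict(list)
    for code, pos in mins:
        idx[code].append(pos)
    return idx


def overlap_detect(
    a: str,
    b: str,
    k: int = DEFAULT_K,
    w: int = DEFAULT_W,
    mode: str = "chain",
    query_id: str = "a",
    target_id: str = "b",
) -> list[AlignmentHit]:
    """Find shared blocks between two sequences in both orientations.

    ``mode='chain'`` bounds each hit by its minimizer chain (plus exact
    extension) — appropriate when looking for contained homology such as a
    gene inside a read.  ``mode='dovetail'`` extends the best diagonal to the
    sequence ends — appropriate for read-overlap semantics.
    """
    a = a.upper()
    b = b.upper()
    a_mins = minimizers(a, k, w)
    hits: list[AlignmentHit] = []
    for orient, bb in (("+", b), ("-", revcomp(b))):
        idx = _build_index(minimizers(bb, k, w))
        for qs, qe, ts, te, ident in _hits_one_orientation(a, bb, idx, a_mins, k, mode):
            if orient == "-":
                ts, te = len(b) - te, len(b) - ts
            hits.append(AlignmentHit(
                query_id=query_id, target_id=target_id,
                q_interval=(qs, qe), t_interval=(ts, te),
                block_length=qe - qs, identity=ident, orientation=orient,
            ))
    hits.sort(key=lambda h: (-h.block_length, h.q_interval))
    return hits


# ---------------------------------------------------------------------------
# Candidate scanning and seed scoring against core genes


def _as_gene_list(core_genes) -> list[tuple[str, str]]:
    out = []
    for i, g in enumerate(core_genes):
        if isinstance(g, GenomeRecord):
            out.append((g.id, g.sequence))
        elif isinstance(g, tuple):
            out.append((g[0], g[1].upper()))
        else:
            out.append((f"gene{i + 1}", g.upper()))
    return out


class CoreGeneIndex:
    """Shared minimizer index over a set of bait (core gene) sequences."""

    def __init__(self, core_genes, k: int = SCAN_K, w: int = SCAN_W):
        self.genes = _as_gene_list(core_genes)
        if not self.genes:
            raise ValueError("core gene set must be non-empty")
        self.k = k
        self.w = w
        self.lengths = {name: len(seq) for name, seq in self.genes}
        self._seqs = {name: seq for name, seq in self.genes}
        # kmer code -> list of (gene name, position, strand)
        self.index: dict[int, list[tuple[str, int, str]]] = defaultdict(list)
        for name, seq in self.genes:
            for code, pos in minimizers(seq, k, w):
                self.index[code].append((name, pos, "+"))
            rc = revcomp(seq)
            for code, pos in minimizers(rc, k, w):
                self.index[code].append((name, pos, "-"))

    def hits(self, read_seq: str, min_block: int,
             min_identity: float = 0.70) -> dict[str, list[AlignmentHit]]:
        """Per-gene alignment hits with block length > min_block.

        ``min_identity`` suppresses chance minimizer chains; a genuine
        core-gene fragment aligns far above it even on noisy long reads.
        """
        read_seq = read_seq.upper()
        matches: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        for code, qp in minimizers(read_seq, self.k, self.w):
            for name, tp, strand in self.index.get(code, ()):
                matches[(name, strand)].append((qp, tp))
        out: dict[str, list[AlignmentHit]] = defaultdict(list)
        for (name, strand), mm in matches.items():
            if len(mm) < MIN_SHARED:
                continue
            gene_seq = self._seqs[name] if strand == "+" else revcomp(self._seqs[name])
            glen = self.lengths[name]
            for cluster in _diagonal_clusters(mm):
                if len(cluster) < MIN_SHARED:
                    continue
                qs = min(q for q, _ in cluster)
                qe = max(q for q, _ in cluster) + self.k
                ts = min(t for _, t in cluster)
                te = max(t for _, t in cluster) + self.k
                qs, qe, ts, te = _greedy_extend(read_seq, gene_seq, qs, qe, ts, te)
                if qe - qs <= min_block:
                    continue
                ident = _identity(read_seq[qs:qe], gene_seq[ts:te])
                if ident < min_identity:
                    continue
                if strand == "-":
                    ts, te = glen - te, glen - ts
                out[name].append(AlignmentHit(
                    query_id="read", target_id=name,
                    q_interval=(qs, qe), t_interval=(ts, te),
                    block_length=qe - qs, identity=ident, orientation=strand,
                ))
        return out


def _coverage_score(per_gene: dict[str, list[AlignmentHit]],
                    lengths: dict[str, int]) -> tuple[int, float]:
    if not per_gene:
        return (0, 0.0)
    fracs = []
    for name, hits in per_gene.items():
        ivs = sorted(h.t_interval for h in hits)
        covered = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        covered += cur_e - cur_s
        fracs.append(min(covered / lengths[name], 1.0))
    return (len(per_gene), sum(fracs) / len(fracs))


def scan_candidates(
    reads: list[LongRead],
    core_genes,
    min_block: int = 50,
    k: int = SCAN_K,
    w: int = SCAN_W,
) -> list[str]:
    """Reads with a core-gene alignment block longer than ``min_block`` bp."""
    idx = core_genes if isinstance(core_genes, CoreGeneIndex) else CoreGeneIndex(core_genes, k, w)
    return [r.id for r in reads if idx.hits(r.sequence, min_block)]


def score_seed(
    read: LongRead,
    core_genes,
    min_block: int = 50,
    k: int = SCAN_K,
    w: int = SCAN_W,
) -> tuple[int, float]:
    """(distinct core genes hit, mean covered fraction of each hit gene)."""
    idx = core_genes if isinstance(core_genes, CoreGeneIndex) else CoreGeneIndex(core_genes, k, w)
    return _coverage_score(idx.hits(read.sequence, min_block), idx.lengths)


def select_seeds(
    reads: list[LongRead],
    core_genes,
    n_seeds: int = 10,
    min_block: int = 50,
) -> list[str]:
    """Rank candidates by (genes hit, completeness); ties by length then id."""
    idx = core_genes if isinstance(core_genes, CoreGeneIndex) else CoreGeneIndex(core_genes)
    scored = []
    for read in reads:
        gh, comp = _coverage_score(idx.hits(read.sequence, min_block), idx.lengths)
        if gh > 0:
            scored.append((-gh, -comp, -len(read.sequence), read.id))
    scored.sort()
    return [rid for *_, rid in scored[:n_seeds]]


# ---------------------------------------------------------------------------
# Iterative recruitment


def recruit_iterative(
    reads: list[LongRead],
    seeds: list[str] | set[str],
    min_overlap: int = 1000,
    min_identity: float = 0.70,
    k: int = DEFAULT_K,
    w: int = DEFAULT_W,
    max_rounds: int | None = None,
) -> RecruitmentResult:
    """Grow the recruited read set by overlap until a round adds nothing.

    Each round, any unrecruited read with a dovetail overlap of at least
    ``min_overlap`` bases and ``min_identity`` identity against any already
    recruited read joins the set.  Additions are batched per round, so the
    final recruited set does not depend on read order.
    """
    seed_ids = set(seeds)
    if not seed_ids:
        raise ValueError("seeds must be non-empty")
    by_id = {r.id: r for r in reads}
    missing = seed_ids - set(by_id)
    if missing:
        raise ValueError(f"seed ids not in read pool: {sorted(missing)}")

    fwd_cache: dict[str, list[tuple[int, int]]] = {}
    rev_cache: dict[str, list[tuple[int, int]]] = {}

    def fwd(rid: str) -> list[tuple[int, int]]:
        if rid not in fwd_cache:
            fwd_cache[rid] = minimizers(by_id[rid].sequence, k, w)
        return fwd_cache[rid]

    def rev(rid: str) -> list[tuple[int, int]]:
        if rid not in rev_cache:
            rev_cache[rid] = minimizers(revcomp(by_id[rid].sequence), k, w)
        return rev_cache[rid]

    # kmer code -> set of unrecruited read ids holding it (either strand)
    pool_index: dict[int, set[str]] = defaultdict(set)
    for r in reads:
        if r.id in seed_ids:
            continue
        for code, _ in fwd(r.id):
            pool_index[code].add(r.id)
        for code, _ in rev(r.id):
            pool_index[code].add(r.id)

    recruited: list[str] = [rid for rid in by_id if rid in seed_ids]
    per_round_added: list[int] = []
    report: list[dict] = []

    idx_cache: dict[tuple[str, str], dict[int, list[int]]] = {}

    def target_index(tid: str, orient: str) -> dict[int, list[int]]:
        key = (tid, orient)
        if key not in idx_cache:
            idx_cache[key] = _build_index(fwd(tid) if orient == "+" else rev(tid))
        return idx_cache[key]

    def qualifies(cand_id: str, target_id: str) -> tuple[bool, int, float]:
        ca = by_id[cand_id].sequence
        a_mins = fwd(cand_id)
        best_block, best_ident = 0, 0.0
        for orient in ("+", "-"):
            tseq = by_id[target_id].sequence if orient == "+" else revcomp(by_id[target_id].sequence)
            idx = target_index(target_id, orient)
            for qs, qe, ts, te, ident in _hits_one_orientation(ca, tseq, idx, a_mins, k, "dovetail"):
                block = min(qe - qs, te - ts)
                if block >= min_overlap and ident >= min_identity:
                    return True, block, ident
                if block > best_block:
                    best_block, best_ident = block, ident
        return False, best_block, best_ident

    frontier = list(recruited)
    round_no = 0
    while True:
        round_no += 1
        # unrecruited reads sharing minimizers with the frontier, per target
        shared: dict[str, Counter] = defaultdict(Counter)
        for tid in frontier:
            for code, _ in fwd(tid):
                for cand in pool_index.get(code, ()):
                    shared[cand][tid] += 1
            for code, _ in rev(tid):
                for cand in pool_index.get(code, ()):
                    shared[cand][tid] += 1
        added: list[str] = []
        for cand in sorted(shared):
            targets = [t for t, c in shared[cand].most_common() if c >= MIN_SHARED]
            for tid in targets:
                ok, block, ident = qualifies(cand, tid)
                if ok:
                    added.append(cand)
                    report.append({"read_id": cand, "round": round_no,
                                   "best_overlap": block, "identity": round(ident, 4)})
                    break
        per_round_added.append(len(added))
        for rid in added:
            recruited.append(rid)
            for code, _ in fwd(rid):
                s = pool_index.get(code)
                if s is not None:
                    s.discard(rid)
            for code, _ in rev(rid):
                s = pool_index.get(code)
                if s is not None:
                    s.discard(rid)
        frontier = added
        if not added:
            break
        if max_rounds is not None and round_no >= max_rounds:
            per_round_added.append(0)
            break

    return RecruitmentResult(
        seed_ids=seed_ids,
        recruited_ids=recruited,
        rounds=len(per_round_added),
        per_round_added=per_round_added,
        report=report,
    )
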