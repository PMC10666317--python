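"""Synthetic organelle genomes, mixed-origin long reads and divergent CDS pairs.

Every detector in this package is exercised against genomes whose features are
*planted* and recorded in a ground-truth manifest: a circular mitogenome with
coding genes (the bait/core set), microsatellites, tandem and dispersed
repeats, verbatim plastid-derived insertions (the MTPT truth), and C->U edit
sites; a circular plastid donor; and a linear nuclear genome carrying diverged
copies of mitochondrial backbone segments (numt-like, the realistic source of
false positives for read recruitment).

Desk-scale defaults are roughly a tenth of real plant organelle sizes (mito
60 kb, plastid 20 kb, nuclear 200 kb), which preserves every threshold
relationship of the detectors (50 bp candidate blocks, 1 kb overlaps, 30 bp
homology fragments).  Reads are drawn from the three genomes at a fixed
mixture with gamma-distributed lengths and uniform substitution+indel errors
(3:1); quality-filtered long-read sets motivate the minimum read length.

All randomness flows through one seeded generator: the same seed gives
byte-identical genomes, manifests and reads.

Backbones are *sanitized*: chance microsatellite runs at detection thresholds
are broken before planting, and guard bases around each planted repeat stop
runs from extending into the backbone, so manifest tallies are exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import GeneModel, GenomeRecord, revcomp
from .editing import EditSite
from .repeats import MISA_THRESHOLDS, SSRHit, _is_primitive, _minimal_rotation, find_ssrs

__all__ = [
    "GeneSpec",
    "SyntheticConfig",
    "TruthManifest",
    "ConfigError",
    "make_genomes",
    "make_reads",
    "make_divergent_pair",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOPS = {"TAA", "TAG", "TGA"}


class ConfigError(ValueError):
    """A feature set that cannot be planted without overlap."""


@dataclass(frozen=True)
class GeneSpec:
    name: str
    cds_length: int  # including the terminal stop codon; divisible by 3
    strand: str = "+"
    n_exons: int = 1
    intron_length: int = 120
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    wraps_origin: bool = False


def _default_genes() -> list[GeneSpec]:
    # a compact core-gene complement; coding lengths (without the stop) echo
    # typical plant-mt genes, so protein lengths match gene-table conventions
    return [
        GeneSpec("atp1", 1530),   # 509 aa
        GeneSpec("atp6", 723, strand="-"),
        GeneSpec("atp9", 228, start_codon="TTG"),
        GeneSpec("cob", 1173),
        GeneSpec("cox1", 1587),   # 528 aa
        GeneSpec("cox2", 786, n_exons=2),
        GeneSpec("cox3", 801, strand="-"),
        GeneSpec("nad1", 981, n_exons=3),
        GeneSpec("nad3", 360),
        GeneSpec("nad4L", 306, start_codon="ACG"),
        GeneSpec("nad6", 621),
        GeneSpec("ccmB", 624, strand="-"),
        GeneSpec("matR", 1971),
        GeneSpec("rps4", 822, wraps_origin=True),
        GeneSpec("sdh3", 315),
    ]


def _default_ssrs() -> list[tuple[str, int]]:
    return [
        ("A", 12), ("A", 11), ("T", 10), ("G", 10),
        ("AG", 6), ("AT", 6), ("CT", 5),
        ("AAG", 5), ("ACT", 4),
        ("AAGT", 3), ("ACTC", 3), ("ATCG", 3),
        ("AACGT", 3),
        ("AACGTC", 3),
    ]


def _default_dispersed() -> list[tuple[int, str]]:
    # the study system shows only forward and palindromic classes
    return [
        (40, "palindromic"), (60, "palindromic"), (80, "palindromic"),
        (120, "palindromic"), (150, "palindromic"), (200, "palindromic"),
        (250, "palindromic"),
        (45, "forward"), (60, "forward"), (90, "forward"),
        (130, "forward"), (180, "forward"), (240, "forward"),
    ]


def _default_insertions() -> list[int]:
    # MTPT fragment lengths; sum 2350 bp = 3.92% of the 60 kb mitogenome
    return [370, 320, 240, 210, 175, 165, 150, 140, 120, 100, 90, 85, 60, 50, 45, 30]


@dataclass
class SyntheticConfig:
    mito_length: int = 60_000
    plastid_length: int = 20_000
    nuclear_length: int = 200_000
    gc_target: float = 0.449
    plastid_gc: float = 0.38
    nuclear_gc: float = 0.36
    gene_specs: list[GeneSpec] = field(default_factory=_default_genes)
    ssr_specs: list[tuple[str, int]] = field(default_factory=_default_ssrs)
    tandem_specs: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(20, 4, 0), (12, 5, 1)])  # (period, copies, substitutions)
    dispersed_specs: list[tuple[int, str]] = field(default_factory=_default_dispersed)
    insertion_specs: list[int] = field(default_factory=_default_insertions)
    numt_specs: list[tuple[int, float]] = field(
        default_factory=lambda: [(2000, 0.80), (2000, 0.80), (2000, 0.80)])
    edits_per_gene: int = 3
    dual_edits: int = 2
    read_mixture: tuple[float, float, float] = (0.05, 0.15, 0.80)  # mito, plastid, nuclear
    n_reads: int = 4000
    read_length_mean: int = 3000
    read_length_min: int = 1500
    error_rate: float = 0.10
    seed: int = 1


@dataclass
class TruthManifest:
    genes: list[GeneModel] = field(default_factory=list)
    gene_cds: dict[str, str] = field(default_factory=dict)
    ssrs: list[SSRHit] = field(default_factory=list)
    tandems: list[dict] = field(default_factory=list)
    dispersed: list[dict] = field(default_factory=list)
    insertions: list[dict] = field(default_factory=list)
    numts: list[dict] = field(default_factory=list)
    edit_sites: list[EditSite] = field(default_factory=list)
    read_labels: dict[str, str] = field(default_factory=dict)

    def validate(self, mito: GenomeRecord, plastid: GenomeRecord,
                 nuclear: GenomeRecord) -> None:
        """Check every recorded feature is present verbatim at its coordinates."""
        for name, cds in self.gene_cds.items():
            gene = next(g for g in self.genes if g.name == name)
            parts = "".join(mito.fetch(s, e) for s, e in gene.exons)
            if gene.strand == "-":
                parts = revcomp(parts)
            assert parts == cds, f"gene {name} does not match its manifest CDS"
        for h in self.ssrs:
            s, e = h.interval
            run = mito.fetch(s, e)
            assert len(run) == h.unit_length * h.copies
            motif = run[: h.unit_length]
            assert run == motif * h.copies, f"SSR at {h.interval} is not perfect"
        for t in self.tandems:
            s, e = t["interval"]
            assert e - s == t["period"] * t["copies"]
        for d in self.dispersed:
            a = mito.fetch(*d["interval_a"])
            b = mito.fetch(*d["interval_b"])
            expect = {
                "forward": b,
                "palindromic": revcomp(b),
                "reverse": b[::-1],
                "complement": revcomp(b)[::-1],
            }[d["orientation"]]
            assert a == expect, f"dispersed pair {d} mismatch"
        for ins in self.insertions:
            assert mito.fetch(*ins["mito_interval"]) == plastid.fetch(*ins["plastid_interval"])
        for nm in self.numts:
            assert len(nuclear.fetch(*nm["nuclear_interval"])) == nm["length"]


# ---------------------------------------------------------------------------
# backbone helpers


def _random_backbone(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _sanitize_ssr_runs(arr: np.ndarray, circular: bool, rng: np.random.Generator,
                       protect: list[tuple[int, int]] | None = None) -> None:
    """Break chance microsatellite runs at MISA thresholds (in place).

    Runs fully inside a protected interval are planted features and stay;
    runs straddling a protected boundary are broken at a base outside it.
    """
    protect = protect or []
    L = len(arr)

    def protected(p: int) -> bool:
        return any(ps <= p < pe or ps <= p + L < pe for ps, pe in protect)

    for _ in range(8):
        g = GenomeRecord("tmp", _arr_to_str(arr), circular=circular)
        hits = find_ssrs(g)
        todo = []
        for h in hits:
            s, e = h.interval
            if any(ps <= s and e <= pe for ps, pe in protect):
                continue  # a planted feature
            todo.append(h)
        if not todo:
            return
        for h in todo:
            s, e = h.interval
            free = [p % L for p in range(s, e) if not protected(p % L) and not protected(p)]
            if not free:
                continue
            mid = free[len(free) // 2]
            old = arr[mid]
            choices = [b for b in _BASES if b != old]
            arr[mid] = choices[int(rng.integers(len(choices)))]
    raise ConfigError("could not sanitize backbone microsatellites")


class _Placer:
    """Tracks occupied intervals and hands out non-overlapping slots."""

    def __init__(self, length: int, rng: np.random.Generator, margin: int = 30):
        self.length = length
        self.rng = rng
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> None:
        self.occupied.append((start, end))
        if end > self.length:  # circular wrap: also block the image near 0
            self.occupied.append((start - self.length, end - self.length))

    def _free(self, start: int, end: int) -> bool:
        s, e = start - self.margin, end + self.margin
        for os_, oe in self.occupied:
            if s < oe and os_ < e:
                return False
        return True

    def place(self, size: int, lo: int = 0, hi: int | None = None,
              min_distance_from: tuple[int, int] | None = None) -> int:
        hi = self.length - size if hi is None else min(hi, self.length - size)
        if hi <= lo:
            raise ConfigError(f"no room for a feature of {size} bp")
        for _ in range(400):
            start = int(self.rng.integers(lo, hi))
            if not self._free(start, start + size):
                continue
            if min_distance_from is not None:
                ms, me = min_distance_from
                gap = max(ms - (start + size), start - me)
                if gap < 2 * size + 50:
                    continue
            self.reserve(start, start + size)
            return start
        raise ConfigError(f"could not place a feature of {size} bp without overlap")


# ---------------------------------------------------------------------------
# gene construction


def _random_cds(rng: np.random.Generator, spec: GeneSpec, gc: float) -> str:
    n = spec.cds_length
    if n % 3 != 0:
        raise ConfigError(f"gene {spec.name}: CDS length {n} not divisible by 3")
    body = _arr_to_str(_random_backbone(rng, n, gc))
    codons = [body[i : i + 3] for i in range(0, n, 3)]
    codons[0] = spec.start_codon
    codons[-1] = spec.stop_codon
    for i in range(1, len(codons) - 1):
        while codons[i] in STOPS:
            codons[i] = _arr_to_str(_random_backbone(rng, 3, gc))
    cds = "".join(codons)
    # no microsatellite runs inside the CDS (keeps genome repeat tallies exact)
    for _ in range(6):
        hits = find_ssrs(GenomeRecord("cds", cds, circular=False))
        if not hits:
            break
        arr = np.frombuffer(cds.encode(), dtype=np.uint8).copy()
        for h in hits:
            s, e = h.interval
            mid = s + (e - s) // 2
            mid -= (mid % 3) - 1  # middle base of a codon: resample the codon
            codon_start = mid - 1
            if codon_start < 3 or codon_start >= len(cds) - 3:
                codon_start = 3
            new = "TAA"
            while new in STOPS:
                new = _arr_to_str(_random_backbone(rng, 3, gc))
            arr[codon_start : codon_start + 3] = np.frombuffer(new.encode(), dtype=np.uint8)
        cds = _arr_to_str(arr)
    if find_ssrs(GenomeRecord("cds", cds, circular=False)):
        raise ConfigError(f"gene {spec.name}: could not draw an SSR-free CDS")
    return cds


def _write_segment(arr: np.ndarray, start: int, segment: str) -> None:
    L = len(arr)
    seg = np.frombuffer(segment.encode(), dtype=np.uint8)
    end = start + len(seg)
    if end <= L:
        arr[start:end] = seg
    else:
        k = L - start
        arr[start:] = seg[:k]
        arr[: end - L] = seg[k:]


def _guard(arr: np.ndarray, pos: int, must_differ_from: int,
           rng: np.random.Generator) -> None:
    """Set arr[pos] to a base different from both its value and a reference."""
    L = len(arr)
    pos %= L
    choices = [b for b in _BASES if b != must_differ_from]
    arr[pos] = choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# genome assembly


def make_genomes(config: SyntheticConfig | None = None
                 ) -> tuple[GenomeRecord, GenomeRecord, GenomeRecord, TruthManifest]:
    """Generate (mito, plastid, nuclear, manifest) from a seeded config."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    manifest = TruthManifest()

    mito = _random_backbone(rng, cfg.mito_length, cfg.gc_target)
    plastid = _random_backbone(rng, cfg.plastid_length, cfg.plastid_gc)
    nuclear = _random_backbone(rng, cfg.nuclear_length, cfg.nuclear_gc)
    _sanitize_ssr_runs(mito, True, rng)
    _sanitize_ssr_runs(plastid, True, rng)

    L = cfg.mito_length
    placer = _Placer(L, rng)

    # the origin-wrapping gene has a fixed slot: reserve it before anything
    # random can land there
    for spec in cfg.gene_specs:
        if spec.wraps_origin:
            span = spec.cds_length + spec.intron_length * (max(spec.n_exons, 1) - 1)
            placer.reserve(L - span // 2, L - span // 2 + span)

    # --- numt source slots (reserved first: largest contiguous features) --
    # the segments are copied into the nuclear genome after all planting;
    # reserving them now keeps them pristine mitochondrial backbone
    numt_sources: list[int] = [placer.place(numt_len)
                               for numt_len, _ in cfg.numt_specs]

    # --- genes ---------------------------------------------------------
    for spec in sorted(cfg.gene_specs, key=lambda s: -s.cds_length):
        cds = _random_cds(rng, spec, cfg.gc_target)
        n_ex = max(spec.n_exons, 1)
        cut = sorted(rng.choice(
            np.arange(3, spec.cds_length - 3, 3), size=n_ex - 1, replace=False
        ).tolist()) if n_ex > 1 else []
        bounds = [0] + cut + [spec.cds_length]
        exon_lengths = [bounds[i + 1] - bounds[i] for i in range(n_ex)]
        span = spec.cds_length + spec.intron_length * (n_ex - 1)
        if spec.wraps_origin:
            start = L - span // 2  # slot pre-reserved before random placement
        else:
            start = placer.place(span)
        genomic = cds if spec.strand == "+" else revcomp(cds)
        glens = exon_lengths if spec.strand == "+" else exon_lengths[::-1]
        exons = []
        pos = start
        offset = 0
        for el in glens:
            exons.append((pos % L, pos % L + el))
            _write_segment(mito, pos % L, genomic[offset : offset + el])
            offset += el
            pos += el + spec.intron_length
        manifest.genes.append(GeneModel(
            name=spec.name, category="protein_coding", strand=spec.strand,
            exons=exons, start_codon=spec.start_codon, stop_codon=spec.stop_codon,
        ))
        manifest.gene_cds[spec.name] = cds

    # --- microsatellites ------------------------------------------------
    for motif, copies in cfg.ssr_specs:
        motif = motif.upper()
        u = len(motif)
        if not _is_primitive(motif):
            raise ConfigError(f"SSR motif {motif} is not primitive")
        if copies < MISA_THRESHOLDS[u]:
            raise ConfigError(f"SSR ({motif}){copies} below the MISA threshold")
        size = u * copies
        start = placer.place(size)
        _write_segment(mito, start, motif * copies)
        _guard(mito, start - 1, mito[(start + u - 1) % L], rng)
        _guard(mito, start + size, mito[(start + size - u) % L], rng)
        manifest.ssrs.append(SSRHit(
            motif=_minimal_rotation(motif), unit_length=u, copies=copies,
            interval=(start, start + size)))

    # --- tandem repeats --------------------------------------------------
    for period, copies, n_subs in cfg.tandem_specs:
        unit = None
        for _ in range(50):
            cand = _arr_to_str(_random_backbone(rng, period, cfg.gc_target))
            region = cand * copies
            if _is_primitive(cand) and not find_ssrs(GenomeRecord("t", region)):
                unit = cand
                break
        if unit is None:
            raise ConfigError(f"could not draw a clean tandem unit of {period} bp")
        region = list(unit * copies)
        sub_positions = rng.choice(len(region), size=n_subs, replace=False) if n_subs else []
        for p in sub_positions:
            old = region[int(p)]
            region[int(p)] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
        region = "".join(region)
        size = len(region)
        start = placer.place(size)
        _write_segment(mito, start, region)
        _guard(mito, start - 1, mito[(start + period - 1) % L], rng)
        _guard(mito, start + size, mito[(start + size - period) % L], rng)
        manifest.tandems.append({
            "period": period, "copies": copies, "n_subs": n_subs,
            "unit": unit, "interval": (start, start + size)})

    # --- dispersed repeats -----------------------------------------------
    for length, orientation in cfg.dispersed_specs:
        if orientation not in ("forward", "palindromic", "reverse", "complement"):
            raise ConfigError(f"unknown dispersed class {orientation}")
        seg = None
        for _ in range(50):
            cand = _arr_to_str(_random_backbone(rng, length, cfg.gc_target))
            if not find_ssrs(GenomeRecord("d", cand)):
                seg = cand
                break
        if seg is None:
            raise ConfigError("could not draw a clean dispersed segment")
        a_start = placer.place(length)
        b_start = placer.place(length, min_distance_from=(a_start, a_start + length))
        second = {
            "forward": seg,
            "palindromic": revcomp(seg),
            "reverse": seg[::-1],
            "complement": revcomp(seg)[::-1],
        }[orientation]
        _write_segment(mito, a_start, seg)
        _write_segment(mito, b_start, second)
        iv_a, iv_b = sorted([(a_start, a_start + length), (b_start, b_start + length)])
        manifest.dispersed.append({
            "orientation": orientation, "interval_a": iv_a, "interval_b": iv_b,
            "length": length})

    # --- plastid-derived insertions (MTPT truth) -------------------------
    p_placer = _Placer(cfg.plastid_length, rng, margin=60)
    for ins_len in cfg.insertion_specs:
        src = p_placer.place(ins_len)
        dst = placer.place(ins_len)
        segment = _arr_to_str(plastid[src : src + ins_len])
        _write_segment(mito, dst, segment)
        manifest.insertions.append({
            "mito_interval": (dst, dst + ins_len),
            "plastid_interval": (src, src + ins_len),
            "length": ins_len,
        })

    # --- numt-like segments in the nuclear genome ------------------------
    n_placer = _Placer(cfg.nuclear_length, rng, margin=60)
    for (numt_len, identity), src in zip(cfg.numt_specs, numt_sources):
        # source: mitochondrial backbone away from planted features
        seg = np.array(mito[src : src + numt_len])
        n_mut = int(round((1.0 - identity) * numt_len))
        positions = rng.choice(numt_len, size=n_mut, replace=False)
        for p in positions:
            old = seg[p]
            choices = [b for b in _BASES if b != old]
            seg[p] = choices[int(rng.integers(len(choices)))]
        dst = n_placer.place(numt_len)
        nuclear[dst : dst + numt_len] = seg
        manifest.numts.append({
            "nuclear_interval": (dst, dst + numt_len),
            "mito_interval": (src, src + numt_len),
            "length": numt_len,
            "identity": identity,
        })

    # --- editing sites ----------------------------------------------------
    for gene in manifest.genes:
        cds = manifest.gene_cds[gene.name]
        n_codons = len(cds) // 3
        eligible = [i + 1 for i in range(3, len(cds) - 3)
                    if cds[i] == "C" and (i % 3) in (0, 1)
                    and 2 <= (i // 3) + 1 <= n_codons - 1]
        take = min(cfg.edits_per_gene, len(eligible))
        chosen = rng.choice(len(eligible), size=take, replace=False)
        for c in sorted(int(x) for x in chosen):
            manifest.edit_sites.append(EditSite(gene=gene.name, cds_position=eligible[c]))
    # dual-position edits: codons with C at positions 1 and 2
    dual_done = 0
    for gene in manifest.genes:
        if dual_done >= cfg.dual_edits:
            break
        cds = manifest.gene_cds[gene.name]
        taken = {s.cds_position for s in manifest.edit_sites if s.gene == gene.name}
        for ci in range(1, len(cds) // 3 - 1):
            p1, p2 = 3 * ci + 1, 3 * ci + 2
            if cds[p1 - 1] == "C" and cds[p2 - 1] == "C" and not ({p1, p2} & taken):
                manifest.edit_sites.append(EditSite(gene=gene.name, cds_position=p1))
                manifest.edit_sites.append(EditSite(gene=gene.name, cds_position=p2))
                dual_done += 1
                break

    mito_rec = GenomeRecord("mito_synth", _arr_to_str(mito), circular=True)
    plastid_rec = GenomeRecord("plastid_synth", _arr_to_str(plastid), circular=True)
    nuclear_rec = GenomeRecord("nuclear_synth", _arr_to_str(nuclear), circular=False)

    # final pass: break chance runs introduced at planting junctions
    final = np.frombuffer(mito_rec.sequence.encode(), dtype=np.uint8).copy()
    protect = ([h.interval for h in manifest.ssrs]
               + [t["interval"] for t in manifest.tandems]
               + [d["interval_a"] for d in manifest.dispersed]
               + [d["interval_b"] for d in manifest.dispersed]
               + [i["mito_interval"] for i in manifest.insertions]
               + [n["mito_interval"] for n in manifest.numts]
               + [iv for g in manifest.genes for iv in g.exons])
    _sanitize_ssr_runs(final, True, rng, protect=protect)
    mito_rec = GenomeRecord("mito_synth", _arr_to_str(final), circular=True)

    manifest.validate(mito_rec, plastid_rec, nuclear_rec)
    return mito_rec, plastid_rec, nuclear_rec, manifest


# ---------------------------------------------------------------------------
# reads


def _apply_read_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform errors at ``rate``: substitutions : indels = 3 : 1."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    r = rng.random(n)
    sub = r < 0.75 * rate
    ins = (r >= 0.75 * rate) & (r < 0.875 * rate)
    dele = (r >= 0.875 * rate) & (r < rate)
    # substitutions: shift to a different base
    idx = np.flatnonzero(sub)
    if len(idx):
        base_of = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(_BASES):
            base_of[b] = i
        cur = base_of[arr[idx]]
        arr[idx] = _BASES[(cur + rng.integers(1, 4, size=len(idx))) % 4]
    # indels via repeat counts (0 = deletion, 2 = insertion after the base)
    repeats = np.ones(n, dtype=np.int64)
    repeats[dele] = 0
    repeats[ins] = 2
    out = np.repeat(arr, repeats)
    if ins.any():
        # the second copy of each duplicated base becomes a random one
        pos_out = np.cumsum(repeats) - 1  # index of last copy of each input base
        second = pos_out[ins]
        out[second] = _BASES[rng.integers(0, 4, size=len(second))]
    return _arr_to_str(out)


def make_reads(
    genomes: tuple[GenomeRecord, GenomeRecord, GenomeRecord],
    manifest: TruthManifest,
    config: SyntheticConfig,
    seed: int | None = None,
) -> list:
    """Simulate labelled long reads from the genome mixture.

    Lengths are ``min + Gamma(shape 3)`` around the configured mean; circular
    genomes are sampled across the origin; per-read labels go into the
    manifest.  Returns a list of `recruitment.LongRead`.
    """
    from .recruitment import LongRead

    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = ["mito", "plastid", "nuclear"]
    probs = np.asarray(config.read_mixture, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError("read mixture fractions must sum to 1")
    by_label = dict(zip(labels, genomes))
    reads: list[LongRead] = []
    scale = max((config.read_length_mean - config.read_length_min) / 3.0, 1.0)
    for i in range(config.n_reads):
        label = labels[int(rng.choice(3, p=probs))]
        g = by_label[label]
        length = int(config.read_length_min + rng.gamma(3.0, scale))
        length = min(length, g.length)
        if g.circular:
            start = int(rng.integers(0, g.length))
        else:
            start = int(rng.integers(0, g.length - length + 1))
        raw = g.fetch(start, start + length)
        if rng.random() < 0.5:
            raw = revcomp(raw)
        seq = _apply_read_errors(raw, config.error_rate, rng)
        rid = f"read{i + 1:05d}"
        reads.append(LongRead(id=rid, sequence=seq, truth_label=label))
        manifest.read_labels[rid] = label
    return reads


# ---------------------------------------------------------------------------
# divergent CDS pairs for Ka/Ks


def make_divergent_pair(
    cds: str,
    omega_target: float,
    ks_target: float,
    seed: int = 0,
) -> tuple[tuple[str, str], dict]:
    """Mutate a CDS codon-wise to approximate synonymous/nonsynonymous budgets.

    ``ks_target`` is the target synonymous substitution proportion per
    synonymous site (uncorrected), and the nonsynonymous budget is
    ``omega_target * ks_target`` per nonsynonymous site.  At most one
    substitution per codon; substitutions creating stop codons are rejected.
    Returns ((original, mutated), realized counts).
    """
    from .molevo import _codon_sites

    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    rng = np.random.default_rng(seed)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n_codons = len(codons)
    S = sum(_codon_sites(c)[0] for c in codons)
    N = 3 * n_codons - S
    syn_budget = int(round(ks_target * S))
    nonsyn_budget = int(round(omega_target * ks_target * N))
    if syn_budget + nonsyn_budget > max(n_codons - 2, 0):
        raise ConfigError("mutation budgets unattainable on this CDS")
    from .core import translate_cds

    mutated = list(codons)
    used: set[int] = set()
    realized = {"synonymous": 0, "nonsynonymous": 0}
    attempts = 0
    max_attempts = 500 * (syn_budget + nonsyn_budget) + 1000
    while (realized["synonymous"] < syn_budget
           or realized["nonsynonymous"] < nonsyn_budget):
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError("mutation budgets unattainable on this CDS")
        ci = int(rng.integers(1, n_codons - 1))
        if ci in used or codons[ci] in STOPS:
            continue
        pos = int(rng.integers(0, 3))
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == codons[ci][pos]:
            continue
        new = codons[ci][:pos] + alt + codons[ci][pos + 1 :]
        if new in STOPS:
            continue
        kind = ("synonymous" if translate_cds(new) == translate_cds(codons[ci])
                else "nonsynonymous")
        budget = syn_budget if kind == "synonymous" else nonsyn_budget
        if realized[kind] >= budget:
            continue
        mutated[ci] = new
        used.add(ci)
        realized[kind] += 1
    return (cds, "".join(mutated)), realized
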