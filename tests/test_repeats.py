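import numpy as np
import pytest

from mitokit.core import GenomeRecord, revcomp
from mitokit.repeats import (
    MISA_THRESHOLDS,
    find_dispersed,
    find_ssrs,
    find_tandems,
    repeat_summary,
)

# ---------------------------------------------------------------------------
# independent SSR oracle: naive maximal periodic run enumeration


def oracle_ssrs(seq: str, thresholds=MISA_THRESHOLDS):
    def primitive(m):
        return all(m != m[:d] * (len(m) // d)
                   for d in range(1, len(m)) if len(m) % d == 0)

    def min_rot(m):
        return min(m[i:] + m[:i] for i in range(len(m)))

    hits = set()
    n = len(seq)
    for u, thr in thresholds.items():
        for i in range(n - u):
            if i > 0 and i - 1 + u < n and seq[i - 1] == seq[i - 1 + u]:
                continue  # not a maximal start
            t = 0
            while i + t + u < n and seq[i + t] == seq[i + t + u]:
                t += 1
            copies = (t + u) // u
            if copies < thr:
                continue
            motif = seq[i : i + u]
            if "N" in motif or not primitive(motif):
                continue
            hits.add((i, u, copies, min_rot(motif)))
    return hits


def embed(background: str, pos: int, insert: str) -> str:
    return background[:pos] + insert + background[pos + len(insert):]


class TestSSRs:
    def test_mono_run_at_threshold(self):
        g = "G" * 3 + "CTC" + "A" * 12 + "GCT" + "G" * 3
        hits = find_ssrs(GenomeRecord("g", g))
        assert [(h.motif, h.copies) for h in hits] == [("A", 12)]

    def test_below_threshold_not_reported(self):
        g = "GCT" + "A" * 9 + "GCT"
        assert find_ssrs(GenomeRecord("g", g)) == []

    def test_motif_canonicalized_to_minimal_rotation(self):
        g = "CCT" + "GA" * 6 + "CTC"
        hits = find_ssrs(GenomeRecord("g", g))
        assert len(hits) == 1 and hits[0].motif == "AG"

    def test_non_primitive_motifs_reported_at_shorter_unit(self):
        g = "CT" + "AT" * 8 + "GC"
        hits = find_ssrs(GenomeRecord("g", g))
        assert [(h.unit_length, h.copies) for h in hits] == [(2, 8)]

    def test_run_crossing_origin_of_circular_genome(self, rng):
        from conftest import random_dna

        bg = random_dna(rng, 400)
        seq = "A" * 7 + bg[7:-7] + "G" + "A" * 6
        g = GenomeRecord("g", seq, circular=True)
        hits = [h for h in find_ssrs(g) if h.motif == "A"]
        assert any(h.copies == 13 and h.interval[0] == len(seq) - 6 for h in hits)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        # low-cardinality alphabet patches make runs likely
        seq = "".join(rng.choice(list(bases), size=5000).tolist())
        seq = embed(seq, 100, "A" * 13)
        seq = embed(seq, 600, "AG" * 7)
        seq = embed(seq, 1200, "CTT" * 5)
        got = {(h.interval[0], h.unit_length, h.copies, h.motif)
               for h in find_ssrs(GenomeRecord("g", seq, circular=False))}
        assert got == oracle_ssrs(seq)

    def test_planted_tallies_match_manifest(self, world):
        hits = find_ssrs(world["mito"])
        planted = {(h.interval, h.motif, h.copies) for h in world["manifest"].ssrs}
        found = {(h.interval, h.motif, h.copies) for h in hits}
        assert found == planted

    def test_origin_rotation_invariance(self, world):
        g = world["mito"]
        offset = 23456
        rotated = g.rotated(offset)
        a = sorted((h.motif, h.unit_length, h.copies) for h in find_ssrs(g))
        b = sorted((h.motif, h.unit_length, h.copies) for h in find_ssrs(rotated))
        assert a == b


class TestTandems:
    def test_exact_unit_times_four(self, rng):
        from conftest import random_dna

        unit = "GATCCATGTTAGCAACTGCA"
        bg = random_dna(rng, 600)
        seq = embed(bg, 200, unit * 4)
        hits = find_tandems(GenomeRecord("g", seq))
        assert hits, "planted tandem not found"
        h = max(hits, key=lambda h: h.score)
        assert h.period == 20
        assert h.percent_match == 100.0
        assert h.interval[0] <= 200 and h.interval[1] >= 200 + 80

    def test_single_substitution_keeps_high_match(self, rng):
        from conftest import random_dna

        unit = "GATCCATGTTAGCAACTGCA"
        region = list(unit * 4)
        region[30] = "A" if region[30] != "A" else "C"
        seq = embed(random_dna(rng, 600), 150, "".join(region))
        hits = find_tandems(GenomeRecord("g", seq))
        h = max(hits, key=lambda h: h.score)
        assert h.period == 20
        assert 82.0 <= h.percent_match < 100.0

    def test_random_sequence_has_no_hit(self, rng):
        from conftest import random_dna

        seq = random_dna(rng, 2000)
        assert find_tandems(GenomeRecord("g", seq), max_period=100) == []
        # brute-force confirmation: best prefix-scored region vs its first unit
        best = 0
        for d in range(2, 101):
            for s in range(0, len(seq) - 2 * d):
                score = 2 * d  # the first unit matches itself implicitly
                m = x = 0
                j = s + d
                while j < len(seq):
                    if seq[j] == seq[s + (j - s) % d]:
                        m += 1
                    else:
                        x += 1
                    cur = 2 * m - 7 * x
                    if cur > best and j - s + 1 >= d:
                        best = cur
                    if x * 7 > 2 * m + 60:
                        break
                    j += 1
        assert best < 50

    def test_planted_tandems_recovered(self, world):
        hits = find_tandems(world["mito"])
        for t in world["manifest"].tandems:
            s, e = t["interval"]
            match = [h for h in hits if h.period == t["period"]
                     and h.interval[0] <= s + 2 and h.interval[1] >= e - 2]
            assert match, f"planted tandem {t} not recovered"
            assert all(h.percent_match >= 82.0 for h in match)


class TestDispersed:
    def test_planted_exact_forward_duplicate(self, rng):
        from conftest import random_dna

        seg = random_dna(rng, 40)
        bg = random_dna(rng, 2000)
        seq = embed(embed(bg, 200, seg), 1500, seg)
        # guard flanks so chance extension cannot blur the planted bounds
        seq = seq[:199] + "A" + seq[200:]
        seq = seq[:1499] + "C" + seq[1500:]
        hits = find_dispersed(GenomeRecord("g", seq), exclude_intervals=[])
        forward = [h for h in hits if h.orientation == "forward"]
        assert len(forward) == 1
        h = forward[0]
        assert h.identity == 1.0
        assert h.interval_a[1] - h.interval_a[0] >= 40

    def test_planted_inverted_duplicate_is_palindromic(self, rng):
        from conftest import random_dna

        seg = random_dna(rng, 40)
        bg = random_dna(rng, 2000)
        seq = embed(embed(bg, 300, seg), 1200, revcomp(seg))
        hits = find_dispersed(GenomeRecord("g", seq), exclude_intervals=[])
        assert any(h.orientation == "palindromic" for h in hits)

    def test_reverse_and_complement_classes(self, rng):
        from conftest import random_dna

        seg = random_dna(rng, 40)
        bg = random_dna(rng, 3000)
        seq = embed(embed(bg, 300, seg), 1200, seg[::-1])
        comp = revcomp(seg)[::-1]
        seq = embed(seq, 2400, comp)
        classes = {h.orientation for h in
                   find_dispersed(GenomeRecord("g", seq), exclude_intervals=[])}
        assert "reverse" in classes and "complement" in classes

    def test_pairs_on_ssr_intervals_are_filtered(self):
        # two (AG)6 runs: dispersed self-match entirely inside SSR intervals
        bg = ("GCTTACGGATC" * 40)
        seq = embed(embed(bg, 50, "AG" * 20), 300, "AG" * 20)
        g = GenomeRecord("g", seq)
        with_filter = find_dispersed(g)
        assert all(not (50 <= h.interval_a[0] < 90) for h in with_filter)

    def test_filter_is_idempotent(self, world):
        man = world["manifest"]
        ssr_iv = [h.interval for h in find_ssrs(world["mito"])]
        tan_iv = [t.interval for t in find_tandems(world["mito"])]
        hits = find_dispersed(world["mito"], exclude_intervals=ssr_iv + tan_iv)
        # no surviving pair overlaps an excluded interval by >50% of its span
        for h in hits:
            for iv in (h.interval_a, h.interval_b):
                for ex in ssr_iv + tan_iv:
                    ov = max(0, min(iv[1], ex[1]) - max(iv[0], ex[0]))
                    assert ov <= 0.5 * (iv[1] - iv[0])
        del man

    def test_planted_class_counts_match_manifest(self, world):
        man = world["manifest"]
        ssr_iv = [h.interval for h in find_ssrs(world["mito"])]
        tan_iv = [t.interval for t in find_tandems(world["mito"])]
        hits = find_dispersed(world["mito"], exclude_intervals=ssr_iv + tan_iv)
        from collections import Counter

        found = Counter(h.orientation for h in hits)
        planted = Counter(d["orientation"] for d in man.dispersed)
        assert found == planted
        # every planted pair recovered within a few bases
        for d in man.dispersed:
            close = [h for h in hits if h.orientation == d["orientation"]
                     and abs(h.interval_a[0] - d["interval_a"][0]) <= 6
                     and abs(h.interval_b[0] - d["interval_b"][0]) <= 6]
            assert close, f"planted dispersed pair {d} not recovered"


class TestSummary:
    def test_totals(self, world):
        ssrs = find_ssrs(world["mito"])
        tandems = find_tandems(world["mito"])
        dispersed = find_dispersed(
            world["mito"],
            exclude_intervals=[h.interval for h in ssrs] + [t.interval for t in tandems])
        s = repeat_summary(ssrs, tandems, dispersed)
        assert s.total == s.n_ssr + s.n_tandem + s.n_dispersed_pairs
        assert s.n_dispersed_copies == 2 * s.n_dispersed_pairs
        assert sum(c for c, _ in s.ssr_unit_distribution.values()) == s.n_ssr

    def test_share_arithmetic(self):
        # printed-style shares: 42 monomers of 137 SSRs -> 30.66%
        assert round(100 * 42 / 137, 2) == 30.66
        assert 137 + 9 + 218 == 364

    def test_empty_inputs(self):
        s = repeat_summary([], [], [])
        assert s.total == 0 and s.ssr_unit_distribution == {}
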