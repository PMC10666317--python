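from itertools import permutations, product

import numpy as np
import pytest

from mitokit.molevo import (
    CodonAlignment,
    classify_selection,
    mlwl,
    ng86,
    pi,
    strip_gap_codons,
)
from mitokit.synthetic import make_divergent_pair

# ---------------------------------------------------------------------------
# independent NG86 oracle (own translation table via Biopython, own pathway
# enumeration)


def _tr(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


STOPS = {"TAA", "TAG", "TGA"}
SENSE = ["".join(p) for p in product("ACGT", repeat=3)
         if "".join(p) not in STOPS]


def oracle_sites(codon: str) -> float:
    syn = 0
    for pos, alt in product(range(3), "ACGT"):
        if alt == codon[pos]:
            continue
        mut = codon[:pos] + alt + codon[pos + 1:]
        if mut not in STOPS and _tr(mut) == _tr(codon):
            syn += 1
    return syn / 3.0


def oracle_diffs(c1: str, c2: str) -> tuple[float, float]:
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in permutations(pos):
        cur, sd, nd, blocked = c1, 0, 0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOPS and nxt != c2:
                blocked = True
            sd += _tr(nxt) == _tr(cur)
            nd += _tr(nxt) != _tr(cur)
            cur = nxt
        results.append((sd, nd, blocked))
    ok = [(s, n) for s, n, b in results if not b] or [(s, n) for s, n, _ in results]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


class TestNG86:
    def test_identical_sequences(self):
        r = ng86(CodonAlignment(["ATGGCTAAA", "ATGGCTAAA"]))
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_synonymous_change_at_fourfold_site(self):
        r = ng86(CodonAlignment(["GCTGGA", "GCTGGG"]))
        assert r.ka == 0.0 and r.ks > 0.0

    def test_site_counts_sum_to_three_per_codon(self, rng):
        codons = rng.choice(SENSE, size=60)
        a = "".join(codons)
        r = ng86(CodonAlignment([a, a]))
        assert r.sites_n + r.sites_s == pytest.approx(3 * 60)

    def test_matches_pathway_enumeration_oracle(self, rng):
        for _ in range(40):
            c1, c2 = rng.choice(SENSE, size=2)
            a = "ATG" + c1 + "GCT"
            b = "ATG" + c2 + "GCT"
            r = ng86(CodonAlignment([a, b]))
            S = (sum(oracle_sites(c) for c in ("ATG", c1, "GCT"))
                 + sum(oracle_sites(c) for c in ("ATG", c2, "GCT"))) / 2
            sd, nd = oracle_diffs(c1, c2)
            N = 9 - S
            assert r.sites_s == pytest.approx(S)
            ps, pn = sd / S, nd / N
            if ps < 0.75:
                assert r.ks == pytest.approx(-0.75 * np.log(1 - 4 * ps / 3), abs=1e-12)
            else:
                assert r.ks is None
            if pn < 0.75:
                assert r.ka == pytest.approx(-0.75 * np.log(1 - 4 * pn / 3), abs=1e-12)

    def test_planted_synonymous_only_mutations_give_ka_zero(self):
        cds = "ATG" + "GCTAAAGGTCTTCCA" * 30 + "TAA"
        (a, b), realized = make_divergent_pair(cds, omega_target=0.0,
                                               ks_target=0.08, seed=5)
        assert realized["nonsynonymous"] == 0
        r = ng86(CodonAlignment([a, b]))
        assert r.ka == 0.0 and r.ks > 0.0


class TestMLWL:
    def test_identical_sequences(self):
        r = mlwl(CodonAlignment(["ATGGCTAAA", "ATGGCTAAA"]))
        assert r.ka == 0.0 and r.ks == 0.0

    def test_transversions_at_fourfold_sites_only(self):
        # GGA -> GGC is a transversion at a fourfold site: synonymous
        a = "GGAGGAGGAGCT"
        b = "GGCGGAGGAGCT"
        r = mlwl(CodonAlignment([a, b]))
        assert r.ks > 0.0 and r.ka == 0.0

    def test_kappa_one_recovers_lwl85_weighting(self):
        cds = "ATG" + "GCTAAAGGTCTTCCAATC" * 25 + "TAA"
        (a, b), _ = make_divergent_pair(cds, 0.5, 0.12, seed=2)
        r = mlwl(CodonAlignment([a, b]), kappa=1.0)
        assert r.sites_s == pytest.approx(r.sites_s)  # defined
        # 1/3 : 2/3 apportioning of twofold sites
        aln = CodonAlignment([a, b])
        r_est = mlwl(aln)
        assert r.sites_s != r_est.sites_s or r.ratio == pytest.approx(r_est.ratio)

    def test_close_to_ng86_at_low_divergence(self):
        rng = np.random.default_rng(11)
        cds = "ATG" + "".join(rng.choice(SENSE, size=300)) + "TAA"
        (a, b), _ = make_divergent_pair(cds, 0.8, 0.08, seed=4)
        r1, r2 = ng86(CodonAlignment([a, b])), mlwl(CodonAlignment([a, b]))
        assert abs(r1.ratio - r2.ratio) / r1.ratio < 0.20


class TestPi:
    def test_two_sequences_two_diffs_over_100(self, rng):
        from conftest import random_dna

        a = random_dna(rng, 99)
        b = a[:10] + ("A" if a[10] != "A" else "C") + a[11:50] \
            + ("G" if a[50] != "G" else "T") + a[51:]
        # pad to 100 gap-free columns by appending one shared base
        a2, b2 = a + "A", b + "A"
        res = pi(CodonAlignment([a2, b2]))
        assert res.pi == pytest.approx(0.02)
        assert res.sites_used == 100

    def test_identical_sequences_give_zero(self):
        res = pi(CodonAlignment(["ACGTACGTA"] * 4))
        assert res.pi == 0.0

    def test_gap_columns_complete_deletion(self):
        res = pi(CodonAlignment(["AC-TACGTA", "ACGTACGTA"]))
        assert res.sites_used == 8

    def test_star_tree_hand_computed(self, rng):
        from conftest import random_dna

        root = random_dna(rng, 200)
        seqs = []
        planted = [3, 5, 0, 2, 4]
        pos_pool = rng.choice(200, size=sum(planted), replace=False)
        k = 0
        for nmut in planted:
            s = list(root)
            for _ in range(nmut):
                p = int(pos_pool[k]); k += 1
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            seqs.append("".join(s))
        # disjoint mutated positions: pairwise diff = sum of the two branches
        n = len(seqs)
        expect = sum(planted[i] + planted[j]
                     for i in range(n) for j in range(i + 1, n))
        expect /= (n * (n - 1) / 2) * 200
        res = pi(CodonAlignment(seqs))
        assert res.pi == pytest.approx(expect)

    def test_reorder_and_duplication_invariance(self, rng):
        from conftest import random_dna

        base = random_dna(rng, 120)
        seqs = [base,
                base[:40] + ("A" if base[40] != "A" else "T") + base[41:],
                base[:90] + ("C" if base[90] != "C" else "G") + base[91:]]
        p1 = pi(CodonAlignment(seqs)).pi
        p2 = pi(CodonAlignment(seqs[::-1])).pi
        assert p1 == pytest.approx(p2)
        # duplicating the whole set rescales the mean-pairwise estimator by
        # exactly 4*C(n,2)/C(2n,2): every original pair appears four times and
        # the n self-pairs contribute zero
        n = 3
        dup = pi(CodonAlignment(seqs + seqs)).pi
        factor = (4 * (n * (n - 1) / 2)) / (2 * n * (2 * n - 1) / 2)
        assert dup == pytest.approx(p1 * factor)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            pi(CodonAlignment(["ACGT"]))


class TestStripGaps:
    def test_codon_columns_with_gaps_removed(self):
        a = "ATG---GCTTAA"
        b = "ATGGGGGCTTAA"
        sa, sb = strip_gap_codons(a, b)
        assert sa == "ATGGCTTAA" and sb == "ATGGCTTAA"


class TestClassifySelection:
    @pytest.mark.parametrize("ratio,expect", [
        (1.8, "positive"), (0.2, "purifying"), (1.0, "neutral"),
        (None, "undetermined"),
    ])
    def test_rules(self, ratio, expect):
        from mitokit.molevo import KaKsResult

        r = KaKsResult(ka=0.1, ks=0.1, ratio=ratio, method="NG86",
                       sites_n=1, sites_s=1)
        assert classify_selection(r) == expect

    def test_ks_zero_is_undetermined(self):
        r = ng86(CodonAlignment(["ATGGCTAAA", "ATGGCGAAA"]))  # nonsyn only? GCT->GCG is syn
        # construct a pure nonsynonymous pair instead
        r = ng86(CodonAlignment(["ATGGCT", "ATGACT"]))
        assert r.ks == 0.0 and classify_selection(r) == "undetermined"
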