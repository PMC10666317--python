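import numpy as np
import pytest

from mitokit.core import revcomp
from mitokit.recruitment import (
    CoreGeneIndex,
    LongRead,
    overlap_detect,
    recruit_iterative,
    scan_candidates,
    score_seed,
    select_seeds,
)


def mutate(seq: str, frac: float, rng) -> str:
    s = list(seq)
    idx = rng.choice(len(s), size=int(round(frac * len(s))), replace=False)
    for i in idx:
        s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
    return "".join(s)


class TestOverlapDetect:
    def test_identical_sequences(self, rng):
        from conftest import random_dna

        seq = random_dna(rng, 2000)
        hits = overlap_detect(seq, seq, mode="dovetail")
        plus = [h for h in hits if h.orientation == "+"]
        assert plus[0].block_length == 2000
        assert plus[0].identity >= 0.99

    def test_reverse_complement_copy(self, rng):
        from conftest import random_dna

        seq = random_dna(rng, 2000)
        hits = overlap_detect(seq, revcomp(seq), mode="dovetail")
        best = hits[0]
        assert best.orientation == "-"
        assert best.block_length == 2000

    def test_identity_estimate_on_20pct_mutated_overlap(self, rng):
        from conftest import random_dna

        overlap = random_dna(rng, 1500)
        a = random_dna(rng, 800) + overlap
        b = mutate(overlap, 0.20, rng) + random_dna(rng, 900)
        hits = overlap_detect(a, b, k=11, w=5, mode="dovetail")
        assert hits, "overlap not detected"
        best = max(hits, key=lambda h: h.block_length)
        assert abs(best.identity - 0.80) <= 0.05
        assert best.block_length >= 1400

    def test_disjoint_sequences_no_hits(self, rng):
        from conftest import random_dna

        assert overlap_detect(random_dna(rng, 900), random_dna(rng, 900)) == []


class TestCandidates:
    @pytest.fixture()
    def genes(self, rng):
        from conftest import random_dna

        return [(f"core{i}", random_dna(rng, 700 + 100 * i)) for i in range(4)]

    def test_read_with_embedded_gene_fragment_is_candidate(self, rng, genes):
        from conftest import random_dna

        read = LongRead("r1", random_dna(rng, 500) + genes[0][1][:600]
                        + random_dna(rng, 500))
        noise = LongRead("r2", random_dna(rng, 1600))
        assert scan_candidates([read, noise], genes) == ["r1"]

    def test_block_of_40bp_is_not_a_candidate(self, rng, genes):
        from conftest import random_dna

        read = LongRead("r1", random_dna(rng, 800) + genes[0][1][:40]
                        + random_dna(rng, 800))
        assert scan_candidates([read], genes) == []

    def test_score_full_genes(self, rng, genes):
        from conftest import random_dna

        spacer = random_dna(rng, 80)
        read = LongRead("r1", genes[0][1] + spacer + genes[1][1] + spacer + genes[2][1])
        gh, comp = score_seed(read, genes)
        assert gh == 3
        assert comp >= 0.99

    def test_score_half_gene(self, rng, genes):
        from conftest import random_dna

        half = len(genes[0][1]) // 2
        read = LongRead("r1", genes[0][1][:half] + random_dna(rng, 900))
        gh, comp = score_seed(read, genes)
        assert gh == 1
        assert 0.47 <= comp <= 0.53

    def test_seed_ranking_matches_brute_force_sort(self, rng, genes):
        from conftest import random_dna

        spacer = random_dna(rng, 60)
        reads = [
            LongRead("a", genes[0][1] + spacer + genes[1][1]),           # 2 genes, full
            LongRead("b", genes[0][1]),                                   # 1 gene, full
            LongRead("c", genes[0][1][:400] + random_dna(rng, 400)),      # 1 gene, partial
            LongRead("d", genes[0][1] + spacer + genes[1][1] + spacer + genes[2][1]),
            LongRead("e", random_dna(rng, 1500)),                         # nothing
        ]
        idx = CoreGeneIndex(genes)
        oracle = []
        for r in reads:
            gh, comp = score_seed(r, idx)
            if gh > 0:
                oracle.append((-gh, -comp, -len(r.sequence), r.id))
        oracle_order = [t[3] for t in sorted(oracle)]
        assert select_seeds(reads, idx, n_seeds=5) == oracle_order
        assert oracle_order[0] == "d" and oracle_order[1] == "a"


class TestRecruitIterative:
    def test_thresholds_at_printed_values(self, rng):
        from conftest import random_dna

        seed_seq = random_dna(rng, 3000)
        ok = mutate(seed_seq[1500:], 0.20, rng) + random_dna(rng, 1500)   # 1.5 kb @ ~80%
        short = random_dna(rng, 1000) + seed_seq[:500] + random_dna(rng, 200)  # 500 bp @ 100%
        reads = [LongRead("seed", seed_seq), LongRead("ok", ok), LongRead("short", short)]
        res = recruit_iterative(reads, ["seed"])
        assert "ok" in res.recruited_ids
        assert "short" not in res.recruited_ids

    def test_chain_recruitment_rounds(self, rng):
        from conftest import random_dna

        s = random_dna(rng, 3000)
        a_tail = random_dna(rng, 1700)
        a = s[1500:] + a_tail                       # overlaps seed by 1.5 kb
        b = a_tail[200:] + random_dna(rng, 1500)    # overlaps only A (1.5 kb)
        reads = [LongRead("s", s), LongRead("a", a), LongRead("b", b)]
        res = recruit_iterative(reads, ["s"])
        assert res.recruited_ids == ["s", "a", "b"]
        assert res.per_round_added == [1, 1, 0]
        assert res.rounds == 3
        round_of = {r["read_id"]: r["round"] for r in res.report}
        assert round_of == {"a": 1, "b": 2}

    def test_empty_seeds_rejected(self, rng):
        from conftest import random_dna

        with pytest.raises(ValueError):
            recruit_iterative([LongRead("x", random_dna(rng, 1500))], [])

    def test_read_order_permutation_invariance(self, rng):
        from conftest import random_dna

        s = random_dna(rng, 3000)
        reads = [LongRead("s", s)]
        pos = 1200
        prev = s
        for i in range(5):
            nxt = prev[pos:] + random_dna(rng, pos)
            reads.append(LongRead(f"r{i}", nxt))
            prev = nxt
        reads.append(LongRead("noise1", random_dna(rng, 2500)))
        reads.append(LongRead("noise2", random_dna(rng, 2500)))
        res1 = recruit_iterative(reads, ["s"])
        rng2 = np.random.default_rng(0)
        perm = list(reads)
        rng2.shuffle(perm)
        res2 = recruit_iterative(perm, ["s"])
        assert set(res1.recruited_ids) == set(res2.recruited_ids)
        assert sorted(res1.per_round_added) == sorted(res2.per_round_added)

    def test_monotone_growth_and_termination(self, rng):
        from conftest import random_dna

        s = random_dna(rng, 3000)
        reads = [LongRead("s", s),
                 LongRead("a", s[1000:] + random_dna(rng, 1000)),
                 LongRead("n", random_dna(rng, 3000))]
        res = recruit_iterative(reads, ["s"])
        assert res.per_round_added[-1] == 0
        assert res.rounds <= len(reads) + 1
        assert res.seed_ids <= set(res.recruited_ids)
        assert sum(res.per_round_added) == len(res.recruited_ids) - len(res.seed_ids)
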