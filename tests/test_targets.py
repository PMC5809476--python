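"""Seed/alignment/duplex predictors and the three-way consensus rule."""

import numpy as np
import pytest

from pxmir._seq import revcomp
from pxmir.targets import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH_GU,
    MATCH_WC,
    MAX_BULGE,
    MISMATCH,
    SEED_POSITIONS,
    TargetSite,
    align_scan,
    consensus_intersect,
    duplex_energy,
    duplex_scan,
    seed_scan,
)

MIR = "TGAGGTAGTAGGTTGTATAGTT"


class TestSeedScan:
    def flank(self, rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_8mer_site(self):
        site = revcomp(MIR[1:8]) + "A"
        utr = "C" * 30 + site + "C" * 30
        out = seed_scan("m", MIR, "u", utr)
        assert len(out) == 1
        assert out[0].site_type == "8mer"
        assert out[0].interval == (30, 38)
        assert utr[out[0].interval[0]:out[0].interval[1]] == site

    def test_7mer_m8_site(self):
        site = revcomp(MIR[1:8]) + "C"   # no A at position 1
        utr = "C" * 30 + site + "C" * 30
        out = seed_scan("m", MIR, "u", utr)
        assert out[0].site_type == "7mer-m8"

    def test_no_core_match_no_site(self):
        # A/C UTR cannot contain the seed complement (which has G or T)
        utr = "AC" * 50
        assert seed_scan("m", MIR, "u", utr) == []

    def test_6mer_excluded_at_default_threshold(self):
        core = revcomp(MIR[1:7])
        # G flanks: not the m8-pairing base (C) and not an A1 adenine
        utr = "G" * 30 + core + "G" * 30
        assert seed_scan("m", MIR, "u", utr) == []
        out = seed_scan("m", MIR, "u", utr, min_type="6mer")
        assert out and out[0].site_type == "6mer"

    def test_matches_naive_window_scan(self):
        rng = np.random.default_rng(8)
        core6 = revcomp(MIR[1:7])
        utr = self.flank(rng, 600)
        found = seed_scan("m", MIR, "u", utr, min_type="6mer")
        naive = [i for i in range(len(utr) - 5) if utr[i:i + 6] == core6]
        assert len(found) == len(naive)


class TestAlignScan:
    def test_perfect_complement_score(self):
        # 22 matches at +5 plus 7 doubled seed positions: 110 + 35 = 145
        utr = revcomp(MIR)
        out = align_scan("m", MIR, "u", utr, threshold=1.0)
        assert out[0].align_score == pytest.approx(145.0)
        assert out[0].interval == (0, 22)

    def test_random_short_utr_rarely_reaches_threshold(self):
        rng = np.random.default_rng(12)
        n_hit = sum(
            bool(align_scan("m", MIR, "u",
                            "".join(rng.choice(list("ACGT"), size=60))))
            for _ in range(20))
        assert n_hit <= 2

    def test_random_hits_score_far_below_perfect_site(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            utr = "".join(rng.choice(list("ACGT"), size=400))
            for s in align_scan("m", MIR, "u", utr):
                assert s.align_score < 110.0

    def test_interval_localized_to_site(self):
        rng = np.random.default_rng(1)
        flank = "".join(rng.choice(list("ACGT"), size=150))
        utr = flank + revcomp(MIR) + flank[::-1]
        out = align_scan("m", MIR, "u", utr)
        (s, e) = out[0].interval
        assert 140 <= s <= 152 and 170 <= e <= 184

    def test_dp_matches_exhaustive_enumeration_small(self):
        """Affine-gap local alignment vs brute-force path enumeration."""
        rng = np.random.default_rng(77)

        def brute(mir, utr):
            rc = revcomp(mir)
            L, n = len(rc), len(utr)
            weights = [2.0 if (L - 1 - j) in SEED_POSITIONS else 1.0
                       for j in range(L)]

            def sub(i, j):
                v, c = utr[i], rc[j]
                if v == c:
                    s = MATCH_WC
                elif (c == "C" and v == "T") or (c == "A" and v == "G"):
                    s = MATCH_GU
                else:
                    s = MISMATCH
                return s * weights[j]

            best = 0.0
            # enumerate all paths: state (i, j, last_op); ops M/I/D
            def rec(i, j, score, last):
                nonlocal best
                best = max(best, score)
                if i < n and j < L:
                    rec(i + 1, j + 1, score + sub(i, j), "M")
                if i < n:
                    w = weights[max(j - 1, 0)]
                    pen = GAP_EXTEND if last == "I" else GAP_OPEN
                    rec(i + 1, j, score + pen * w, "I")
                if j < L:
                    w = weights[j]
                    pen = GAP_EXTEND if last == "D" else GAP_OPEN
                    rec(i, j + 1, score + pen * w, "D")

            for i0 in range(n):
                for j0 in range(L):
                    rec(i0, j0, 0.0, None)
            return best

        for _ in range(6):
            mir = "".join(rng.choice(list("ACGT"), size=7))
            utr = "".join(rng.choice(list("ACGT"), size=9))
            out = align_scan("m", mir + "A", "u", utr, threshold=0.5)
            got = max((s.align_score for s in out), default=0.0)
            want = brute(mir + "A", utr)
            assert got == pytest.approx(want), (mir, utr)


class TestDuplex:
    def test_perfect_complement_beats_single_mismatch(self):
        target = revcomp(MIR)
        e0 = duplex_energy(MIR, target)
        for pos in (5, 11, 16):
            mm = list(target)
            mm[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mm[pos]]
            assert e0 < duplex_energy(MIR, "".join(mm))

    def test_energy_nonpositive(self):
        assert duplex_energy("ACGT" * 3, "ACGT" * 3) <= 0

    def test_dp_matches_exhaustive_pairing_enumeration(self):
        """All monotone pairings with bounded bulges, scored identically."""
        from pxmir.fold import STACK_ENERGY

        def pairs_ok(u, m):
            k = (u + m).replace("T", "U")
            return k in STACK_ENERGY

        def brute(mir, win):
            n, L = len(win), len(mir)
            best = 0

            def rec(pairs):
                nonlocal best
                # score this pairing
                e = 0
                for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
                    gap = (i2 - i1 - 1) + (j1 - j2 - 1)
                    if gap == 0:
                        e += STACK_ENERGY[(win[i2] + mir[j2]).replace("T", "U")]
                    else:
                        e += gap * 20
                best = min(best, e)
                i_min = pairs[-1][0] + 1 if pairs else 0
                j_max = pairs[-1][1] - 1 if pairs else L - 1
                for i in range(i_min, n):
                    if pairs and i - pairs[-1][0] - 1 > MAX_BULGE:
                        break
                    for j in range(j_max, -1, -1):
                        if pairs and pairs[-1][1] - j - 1 > MAX_BULGE:
                            continue
                        if pairs_ok(win[i], mir[j]):
                            rec(pairs + [(i, j)])
            rec([])
            return best / 10.0

        rng = np.random.default_rng(42)
        for _ in range(8):
            mir = "".join(rng.choice(list("ACGT"), size=6))
            win = "".join(rng.choice(list("ACGT"), size=8))
            assert duplex_energy(mir, win) == pytest.approx(brute(mir, win)), \
                (mir, win)


class TestConsensus:
    def site(self, pred, iv=(10, 30)):
        return TargetSite("m", "t", iv, predictors_hit=frozenset({pred}))

    def test_two_predictor_site_not_consensus(self):
        cons, venn = consensus_intersect(
            [self.site("seed")], [self.site("align")], [])
        assert cons == [] and venn["seed&align"] == 1
        assert venn["seed&align&duplex"] == 0

    def test_three_way_overlap_is_consensus(self):
        cons, venn = consensus_intersect(
            [self.site("seed", (10, 18))],
            [self.site("align", (5, 27))],
            [self.site("duplex", (15, 40))])
        assert len(cons) == 1 and cons[0].consensus
        assert venn["seed&align&duplex"] == 1

    def test_disjoint_intervals_do_not_merge(self):
        cons, venn = consensus_intersect(
            [self.site("seed", (10, 18))],
            [self.site("align", (50, 70))],
            [self.site("duplex", (100, 130))])
        assert cons == [] and venn["seed&align"] == 0

    def test_triple_bounded_by_pairwise(self, pipeline_result):
        v = pipeline_result.venn
        triple = v["seed&align&duplex"]
        assert triple <= min(v["seed&align"], v["seed&duplex"],
                             v["align&duplex"])

    def test_reversed_utr_loses_plus_orientation_sites(self):
        site = revcomp(MIR[1:]) + "A"
        rng = np.random.default_rng(3)
        flank = "".join(rng.choice(list("ACGT"), size=100))
        utr = flank + site + flank[::-1]
        assert seed_scan("m", MIR, "u", utr)
        assert seed_scan("m", MIR, "u", utr[::-1]) == []


class TestSyntheticRecovery:
    def test_all_strong_sites_consensus_positive(self, pipeline_result):
        truth = pipeline_result.study.truth
        cons = pipeline_result.consensus_sites
        strong = [s for s in truth.site_truth
                  if s["site_type"] == "strong_8mer"]
        assert strong
        for s in strong:
            assert any(c.mirna == s["mirna"] and c.transcript == s["utr"]
                       and c.interval[0] < s["end"]
                       and s["start"] < c.interval[1]
                       for c in cons), s

    def test_decoy_utrs_mostly_consensus_negative(self, pipeline_result):
        truth = pipeline_result.study.truth
        strong_utrs = {s["utr"] for s in truth.site_truth
                       if s["site_type"] == "strong_8mer"}
        decoys = set(pipeline_result.study.utrs) - strong_utrs
        positive = {c.transcript
                    for c in pipeline_result.consensus_sites} - strong_utrs
        assert len(positive) / len(decoys) <= 0.05
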