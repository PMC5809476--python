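"""Filter cascade, tag collapsing, mapping and annotation priority."""

import numpy as np
import pytest

from pxmir._seq import revcomp
from pxmir.reads import (
    CleanTag,
    RawRead,
    annotate_tags,
    clean_reads,
    collapse_tags,
    find_adapter3,
    length_distribution,
    map_tags,
    parse_gff3,
)

A3 = "TGGAATTCTCGGGTGCCAAGG"
A5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def read(seq, qual=None, rid="r1"):
    return RawRead(rid, seq, qual if qual is not None else "I" * len(seq))


def perfect(insert):
    return read(insert + A3 + "ACGT")


class TestCleanReads:
    def test_all_perfect_reads_survive(self):
        reads = [perfect("ACGTACGTACGTACGTACGTAC") for _ in range(5)]
        inserts, st = clean_reads(reads, A3, A5)
        assert st.clean_total == st.raw_total == 5
        assert (st.removed_low_quality == st.removed_5prime_contaminant
                == st.removed_no_3adapter_or_insert == st.removed_short == 0)
        assert all(i == "ACGTACGTACGTACGTACGTAC" for i in inserts)

    def test_short_insert_counted_as_short(self):
        r = perfect("ACGTACGTACGTACGT")  # 16 nt with valid adapter
        _, st = clean_reads([r], A3, A5)
        assert st.removed_short == 1 and st.clean_total == 0

    def test_low_quality_takes_priority(self):
        seq = "ACGTACGTACGTACGTACGTAC" + A3
        bad_q = chr(33 + 2) * len(seq)  # every base far below Q20
        _, st = clean_reads([read(seq, bad_q)], A3, A5)
        assert st.removed_low_quality == 1
        assert st.removed_no_3adapter_or_insert == 0

    def test_5prime_contaminant_detected(self):
        r = perfect("ACGTACGTACGTACGTACGTAC")
        r.sequence = A5[:10] + r.sequence
        r.quality = "I" * len(r.sequence)
        _, st = clean_reads([r], A3, A5)
        assert st.removed_5prime_contaminant == 1

    def test_missing_adapter_detected(self):
        _, st = clean_reads([read("ACGTACGTACGTACGTACGTACACACACAC")], A3, A5)
        assert st.removed_no_3adapter_or_insert == 1

    def test_adapter_with_one_mismatch_still_found(self):
        a3_mut = "A" + A3[1:]
        r = read("ACGTACGTACGTACGTACGTAC" + a3_mut)
        inserts, st = clean_reads([r], A3, A5)
        assert st.clean_total == 1 and inserts == ["ACGTACGTACGTACGTACGTAC"]

    def test_length_quality_mismatch_raises_with_record_id(self):
        bad = RawRead("bad-rec", "ACGT", "II")
        with pytest.raises(ValueError, match="bad-rec"):
            clean_reads([bad], A3, A5)

    def test_conservation_invariant(self, study, pipeline_result):
        for lib, st in pipeline_result.stats.items():
            removed = (st.removed_low_quality + st.removed_5prime_contaminant
                       + st.removed_no_3adapter_or_insert + st.removed_short)
            assert st.raw_total == st.clean_total + removed
            assert st.mapped_total <= st.clean_total


def test_find_adapter3_first_match_wins():
    insert = "ACGTACGTACGTACGTACGTAC"
    seq = insert + A3 + insert + A3
    assert find_adapter3(seq, A3) == len(insert)


class TestCollapse:
    def test_counts_per_library(self):
        tags = collapse_tags({"lib1": ["A" * 20] * 3, "lib2": ["A" * 20] * 2})
        assert len(tags) == 1 and tags[0].counts == {"lib1": 3, "lib2": 2}

    def test_per_library_conservation(self):
        ins = {"a": ["A" * 20, "C" * 20, "A" * 20], "b": ["G" * 20]}
        tags = collapse_tags(ins)
        for lib, lst in ins.items():
            assert sum(t.counts.get(lib, 0) for t in tags) == len(lst)

    def test_order_descending_total_then_lexicographic(self):
        tags = collapse_tags({"a": ["C" * 20, "C" * 20, "A" * 20, "G" * 20]})
        assert [t.sequence for t in tags] == ["C" * 20, "A" * 20, "G" * 20]


class TestLengthDistribution:
    def test_single_tag(self):
        tags = [CleanTag("A" * 22, {"lib": 10})]
        assert length_distribution(tags) == {"lib": {22: 1.0}}

    def test_empty_library_no_crash(self):
        assert length_distribution([]) == {}

    def test_frequencies_sum_to_one(self, pipeline_result):
        for lib, hist in length_distribution(pipeline_result.tags).items():
            assert sum(hist.values()) == pytest.approx(1.0)

    def test_synthetic_modes_at_22_and_28(self, pipeline_result):
        for lib in pipeline_result.config.simulation.libraries:
            h = length_distribution(pipeline_result.tags)[lib]
            assert h[22] > h[21] and h[22] > h[23]
            assert h[28] > h[27] and h[28] > h[29]


class TestMapTags:
    def test_forward_and_reverse_hits_match_naive_scan(self):
        rng = np.random.default_rng(3)
        genome = {"c": "".join(rng.choice(list("ACGT"), size=2000))}
        tags = [CleanTag(genome["c"][100:122], {"l": 1}),
                CleanTag(revcomp(genome["c"][50:72]), {"l": 1}),
                CleanTag("ACGTN" * 4, {"l": 1})]
        hits = map_tags(tags, genome)

        def naive(q):
            out = []
            for query, strand in ((q, "+"), (revcomp(q), "-")):
                for i in range(len(genome["c"]) - len(q) + 1):
                    if genome["c"][i:i + len(q)] == query:
                        out.append(("c", i, i + len(q), strand))
            return sorted(out)

        for t in tags:
            assert hits[t.sequence] == naive(t.sequence)

    def test_planted_mirna_tags_map_to_their_loci(self, pipeline_result):
        truth = pipeline_result.study.truth
        hits = pipeline_result.hits
        for name, info in truth.mirna_truth.items():
            mature = info["mature"]
            if mature not in hits:
                continue
            contig, s, e, _ = info["locus"]
            assert any(h[0] == contig and s <= h[1] and h[2] <= e
                       for h in hits[mature]), name


class TestAnnotate:
    def feats(self):
        return [("c", 100, 200, "rRNA"), ("c", 150, 260, "known_miRNA"),
                ("c", 300, 400, "intron")]

    def test_priority_rrna_over_mirna(self):
        tags = [CleanTag("A" * 22, {"l": 1})]
        hits = {"A" * 22: [("c", 140, 162, "+")]}  # overlaps rRNA and miRNA
        assert annotate_tags(tags, hits, self.feats())["A" * 22] == "rRNA"

    def test_intron_only(self):
        tags = [CleanTag("C" * 22, {"l": 1})]
        hits = {"C" * 22: [("c", 310, 332, "+")]}
        assert annotate_tags(tags, hits, self.feats())["C" * 22] == "intron"

    def test_no_hit_is_unannotated(self):
        tags = [CleanTag("G" * 22, {"l": 1})]
        assert annotate_tags(tags, {}, self.feats())["G" * 22] == "unannotated"

    def test_feature_order_irrelevant(self):
        tags = [CleanTag("A" * 22, {"l": 1})]
        hits = {"A" * 22: [("c", 140, 162, "+")]}
        fwd = annotate_tags(tags, hits, self.feats())
        rev = annotate_tags(tags, hits, list(reversed(self.feats())))
        assert fwd == rev

    def test_class_totals_match_generator_ledger(self, pipeline_result):
        truth = pipeline_result.study.truth
        ann = pipeline_result.annotation
        for lib in pipeline_result.config.simulation.libraries:
            totals: dict[str, int] = {}
            for t in pipeline_result.tags:
                totals[ann[t.sequence]] = (totals.get(ann[t.sequence], 0)
                                           + t.counts.get(lib, 0))
            for cls, expect in truth.class_truth[lib].items():
                if cls == "background":
                    continue
                assert totals.get(cls, 0) == expect, (lib, cls)
            known = sum(v["realized_counts"][lib]
                        for v in truth.mirna_truth.values() if v["known"])
            assert totals.get("known_miRNA", 0) == known


class TestGff3:
    def test_roundtrip_through_writer(self, tmp_path):
        from pxmir.simulate import write_gff3
        recs = [("chr1", 10, 60, "rRNA", "r1"),
                ("chr1", 100, 152, "miRNA_primary_transcript", "m1")]
        path = tmp_path / "x.gff3"
        write_gff3(recs, path)
        feats = parse_gff3(path)
        assert feats == [("chr1", 10, 60, "rRNA"),
                         ("chr1", 100, 152, "known_miRNA")]

    def test_malformed_gff_raises(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\trRNA\tnotanumber\t5\n")
        with pytest.raises(ValueError):
            parse_gff3(p)
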