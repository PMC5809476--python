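"""Generator determinism, config validation and ledger invariants."""

import math

import numpy as np
import pytest

from pxmir.simulate import (
    GroundTruth,
    PlacementError,
    SimulationConfig,
    generate_all,
    generate_genome,
    generate_qpcr_table,
)


class TestConfigValidation:
    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_quality_fail=1.5)

    def test_failure_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_quality_fail=0.5, frac_no3adapter=0.6)

    def test_fold_change_shape_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_de_mirnas=2, de_fold_changes=((2.0,),))

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_utrs=0)


class TestGenome:
    def test_feature_counts_by_construction(self):
        cfg = SimulationConfig(seed=5, n_known_mirnas=20)
        genome, gff, known, novel = generate_genome(cfg)
        assert len(genome["chr1"]) == cfg.genome_length
        prec = [r for r in gff if r[3] == "miRNA_primary_transcript"]
        assert len(prec) == 20 and len(known) == 20

    def test_deterministic_per_seed(self):
        a = generate_genome(SimulationConfig(seed=7))
        b = generate_genome(SimulationConfig(seed=7))
        assert a[0] == b[0] and a[1] == b[1]

    def test_infeasible_placement_raises(self):
        with pytest.raises(PlacementError):
            generate_genome(SimulationConfig(seed=1, genome_length=5000))

    def test_features_do_not_overlap(self, study):
        spans = sorted((s, e) for _c, s, e, _t, _n in study.gff_records)
        assert all(b0 >= a1 for (a0, a1), (b0, b1) in zip(spans, spans[1:]))

    def test_precursor_embedded_at_locus(self, study):
        for info in study.truth.mirna_truth.values():
            c, s, e, _ = info["locus"]
            assert study.genome[c][s:e] == info["precursor"]


class TestLibraries:
    def test_byte_identical_outputs_for_same_seed(self):
        cfg = dict(seed=9, reads_per_library=2000)
        a = generate_all(SimulationConfig(**cfg))
        b = generate_all(SimulationConfig(**cfg))
        assert a.libraries == b.libraries
        assert a.utrs == b.utrs and a.term_rows == b.term_rows
        assert a.qpcr_rows == b.qpcr_rows

    def test_planted_failure_counts(self, study):
        cfg = study.config
        for lib in cfg.libraries:
            ft = study.truth.filter_truth[lib]
            assert ft["quality_fail"] == round(
                cfg.frac_quality_fail * cfg.reads_per_library)
            assert ft["short"] == round(
                cfg.frac_short * cfg.reads_per_library)

    def test_every_read_attributed_and_conserved(self, study):
        # ledger completeness: read ids carry their class; totals conserve
        for lib, reads in study.libraries.items():
            assert len(reads) == study.config.reads_per_library
            n_fail = sum(1 for rid, _s, _q in reads
                         if rid.split("|")[1].startswith("fail_"))
            assert n_fail == sum(study.truth.filter_truth[lib].values())

    def test_fold_change_encoded_in_expected_counts(self, study):
        truth = study.truth
        for name, fcs in truth.de_truth.items():
            exp = truth.mirna_truth[name]["expected_counts"]
            for trt, lfc in fcs.items():
                ratio = exp[trt] / exp["control"]
                assert math.log2(ratio) == pytest.approx(lfc, abs=0.05)

    def test_site_intervals_inside_utrs(self, study):
        for s in study.truth.site_truth:
            utr = study.utrs[s["utr"]]
            assert 0 <= s["start"] < s["end"] <= len(utr)

    def test_planted_site_count(self, study):
        cfg = study.config
        strong = [s for s in study.truth.site_truth
                  if s["site_type"] == "strong_8mer"]
        assert len(strong) == cfg.n_de_mirnas * cfg.planted_sites_per_de_mirna


class TestQpcrGenerator:
    def test_noise_free_table_encodes_exact_rq(self):
        cfg = SimulationConfig(seed=2, qpcr_noise_sd=0.0)
        truth = GroundTruth()
        truth.de_truth = {"m1": {"2h": 2.0, "4h": -1.0, "6h": 0.0}}
        rows = generate_qpcr_table(cfg, truth)
        by_group = {}
        for r in rows:
            by_group.setdefault(r["group"], []).append(
                r["ct_target"] - r["ct_reference"])
        cal = np.mean(by_group["control"])
        assert 2 ** -(np.mean(by_group["2h"]) - cal) == pytest.approx(4.0)
        assert 2 ** -(np.mean(by_group["4h"]) - cal) == pytest.approx(0.5)
        assert 2 ** -(np.mean(by_group["6h"]) - cal) == pytest.approx(1.0)

    def test_noisy_recovery_within_three_sd(self):
        cfg = SimulationConfig(seed=4, qpcr_noise_sd=0.1)
        truth = GroundTruth()
        truth.de_truth = {"m1": {"2h": 2.0, "4h": 2.0, "6h": 2.0}}
        rows = generate_qpcr_table(cfg, truth)
        dct = {}
        for r in rows:
            dct.setdefault(r["group"], []).append(
                r["ct_target"] - r["ct_reference"])
        cal = np.mean(dct["control"])
        for trt in ("2h", "4h", "6h"):
            rq = 2 ** -(np.mean(dct[trt]) - cal)
            # sd of mean ddCt ~ 0.1*sqrt(2/3+2/3); generous 3-sd band in log2
            assert abs(math.log2(rq) - 2.0) < 3 * 0.12
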