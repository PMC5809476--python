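"""Synthetic small-RNA-seq study generator with a ground-truth ledger.

Emulates the statistical structure of a four-library destruxin-response
experiment (control plus three post-injection time points): a reference
genome carrying embedded miRNA precursors and structural-RNA loci, a mature
miRNA catalog, raw FASTQ libraries with a bimodal insert-length profile
(modes at 22 nt, miRNA-sized, and 28 nt, piRNA-sized) and planted cleaning
failures at exact counts, a 3'-UTR set with planted binding sites, term
annotation maps with planted enriched terms, and a qPCR Ct table whose
relative quantities encode the planted fold-changes.

Every read is attributable to exactly one ground-truth class and all
planted quantities are recorded in :class:`GroundTruth`, so each pipeline
stage can be validated against exact expectations.

Determinism: one seed drives independent per-stage substreams
(``numpy.random.SeedSequence.spawn``), so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._seq import revcomp, to_rna
from .reads import (
    ADAPTER5_MIN_MATCH,
    contains_internal_adapter,
    find_adapter3,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlacementError",
    "generate_genome",
    "generate_read_libraries",
    "generate_transcriptome_with_sites",
    "generate_term_maps",
    "generate_qpcr_table",
    "generate_all",
    "SyntheticStudy",
]

LIBRARIES = ["control", "2h", "4h", "6h"]

# structural / genic feature classes embedded in the genome:
# class -> (n_loci, locus_length, GFF3 feature type)
FEATURE_PLAN = {
    "rRNA": (2, 150, "rRNA"),
    "tRNA": (4, 72, "tRNA"),
    "snRNA": (3, 110, "snRNA"),
    "snoRNA": (3, 90, "snoRNA"),
    "repeat": (3, 220, "repeat_region"),
    "exon": (4, 300, "exon"),
    "intron": (4, 300, "intron"),
}

#: insert-length profile of non-miRNA small RNAs (piRNA-sized mode at 28)
_OTHER_LEN = list(range(18, 31))
_OTHER_LEN_W = np.array([2, 2, 2, 2, 3, 3, 4, 5, 6, 7, 14, 6, 3], dtype=float)
_OTHER_LEN_W /= _OTHER_LEN_W.sum()


class PlacementError(RuntimeError):
    """Features cannot be placed in the genome without overlap."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment."""

    seed: int = 0
    libraries: tuple[str, ...] = tuple(LIBRARIES)
    reads_per_library: int = 30_000
    genome_length: int = 100_000
    n_known_mirnas: int = 30
    n_novel_mirnas: int = 6
    n_de_mirnas: int = 6
    #: linear fold-change per DE miRNA (rows) per treatment library (cols)
    de_fold_changes: tuple[tuple[float, ...], ...] | None = None
    frac_len22_peak: float = 0.35
    frac_len28_peak: float = 0.14
    frac_quality_fail: float = 0.010
    frac_no3adapter: float = 0.010
    frac_5contaminant: float = 0.005
    frac_short: float = 0.010
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    n_utrs: int = 60
    planted_sites_per_de_mirna: int = 2
    utr_length: int = 400
    qpcr_noise_sd: float = 0.10
    qpcr_replicates: int = 3
    #: per-library expected read share of each DE miRNA in the control
    de_base_proportion: float = 0.006
    mature_length: int = 22
    loop_length: int = 8
    #: abundant tags from unstructured genomic regions — negative controls
    #: for novel-miRNA discovery
    n_decoy_loci: int = 8
    decoy_reads_per_library: int = 25

    def __post_init__(self):
        if self.de_fold_changes is None:
            n_trt = len(self.libraries) - 1
            fcs = []
            for i in range(self.n_de_mirnas):
                fc = 4.0 if i % 2 == 0 else 0.25
                fcs.append(tuple([fc] * n_trt))
            self.de_fold_changes = tuple(fcs)
        self.validate()

    def validate(self) -> None:
        fracs = [self.frac_quality_fail, self.frac_no3adapter,
                 self.frac_5contaminant, self.frac_short,
                 self.frac_len22_peak, self.frac_len28_peak]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all proportions must lie in [0, 1]")
        if (self.frac_quality_fail + self.frac_no3adapter
                + self.frac_5contaminant + self.frac_short) > 1:
            raise ValueError("failure proportions sum above 1")
        for name in ("reads_per_library", "genome_length", "n_known_mirnas",
                     "n_novel_mirnas", "n_utrs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_de_mirnas > self.n_known_mirnas:
            raise ValueError("more DE miRNAs than known miRNAs")
        if len(self.de_fold_changes) != self.n_de_mirnas:
            raise ValueError("need one fold-change row per DE miRNA")
        n_trt = len(self.libraries) - 1
        if any(len(row) != n_trt for row in self.de_fold_changes):
            raise ValueError("need one fold-change per treatment library")
        failure_total = int(round(self.reads_per_library * (
            self.frac_quality_fail + self.frac_no3adapter
            + self.frac_5contaminant + self.frac_short)))
        if self.reads_per_library < failure_total:
            raise ValueError("reads_per_library below planted failure total")

    @property
    def treatments(self) -> list[str]:
        return list(self.libraries[1:])

    @property
    def control(self) -> str:
        return self.libraries[0]


@dataclass
class GroundTruth:
    """Machine-readable ledger of everything that was planted."""

    mirna_truth: dict = field(default_factory=dict)
    decoy_truth: list = field(default_factory=list)
    de_truth: dict = field(default_factory=dict)
    filter_truth: dict = field(default_factory=dict)
    class_truth: dict = field(default_factory=dict)
    site_truth: list = field(default_factory=list)
    term_truth: list = field(default_factory=list)
    utr_sequences: dict = field(default_factory=dict)
    qpcr_true_rq: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _clean_insert_ok(seq: str, cfg: SimulationConfig) -> bool:
    """A sequence that will never trip the adapter filters prematurely."""
    if contains_internal_adapter(seq, cfg.adapter3):
        return False
    if cfg.adapter5[:ADAPTER5_MIN_MATCH] in seq:
        return False
    return True


def _rand_clean_seq(rng, n, cfg, *, tries: int = 1000) -> str:
    for _ in range(tries):
        s = _rand_seq(rng, n)
        if _clean_insert_ok(s, cfg):
            return s
    raise RuntimeError("could not draw an adapter-free sequence")


DECOY_REGION_LEN = 162   # tag at offset 70, so both excisions fit inside
DECOY_TAG_OFFSET = 70


def _make_decoy_region(rng, cfg) -> tuple[str, int]:
    """A pair-free low-complexity region (A/C only, so no Watson-Crick or
    wobble pair can form): an abundant tag here reaches the novel-miRNA
    discoverer but must fail its MFE criterion."""
    for _ in range(100):
        region = "".join(rng.choice(list("AC"), size=DECOY_REGION_LEN))
        if _clean_insert_ok(region, cfg):
            return region, DECOY_TAG_OFFSET
    raise RuntimeError("could not build an unstructured decoy region")


def _make_precursor(rng, cfg) -> tuple[str, str]:
    """(mature, precursor): mature 5p arm, loop, perfect-complement star."""
    while True:
        mature = _rand_clean_seq(rng, cfg.mature_length, cfg)
        # GC-rich enough for a deep hairpin
        if (mature.count("G") + mature.count("C")) < 0.45 * len(mature):
            continue
        loop = _rand_clean_seq(rng, cfg.loop_length, cfg)
        prec = mature + loop + revcomp(mature)
        if _clean_insert_ok(prec, cfg):
            return mature, prec


def _place_features(rng, genome_len: int, lengths: list[int],
                    *, tries: int = 2000) -> list[int]:
    """Non-overlapping random starts for features of the given lengths."""
    placed: list[tuple[int, int]] = []
    starts = []
    for L in lengths:
        if L > genome_len:
            raise PlacementError(f"feature of length {L} exceeds genome")
        for _ in range(tries):
            s = int(rng.integers(0, genome_len - L + 1))
            if all(s + L + 10 <= a or b + 10 <= s for a, b in placed):
                placed.append((s, s + L))
                starts.append(s)
                break
        else:
            raise PlacementError(
                "could not place all features without overlap; "
                "increase genome_length")
    return starts


def generate_genome(config: SimulationConfig, truth: GroundTruth | None = None,
                    ) -> tuple[dict[str, str], list, list, list]:
    """Build the reference genome and its feature annotation.

    Returns (genome, gff_records, known_catalog, novel_catalog) where
    gff_records are (contig, start0, end0, ftype, name) tuples, and each
    catalog entry is a dict with name/mature/precursor/locus.
    """
    truth = truth if truth is not None else GroundTruth()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    feature_lengths = []
    feature_meta = []  # (class, gff_type, name)
    for cls, (n, L, gff_type) in FEATURE_PLAN.items():
        for i in range(n):
            feature_lengths.append(L)
            feature_meta.append((cls, gff_type, f"{cls}-{i + 1}"))
    prec_len = config.mature_length * 2 + config.loop_length
    for i in range(config.n_known_mirnas):
        feature_lengths.append(prec_len)
        feature_meta.append(("known_mirna", "miRNA_primary_transcript",
                             f"pxy-mir-{i + 1}"))
    for i in range(config.n_novel_mirnas):
        feature_lengths.append(prec_len)
        feature_meta.append(("novel_mirna", None, f"pxy-novel-{i + 1}"))
    for i in range(config.n_decoy_loci):
        feature_lengths.append(DECOY_REGION_LEN)
        feature_meta.append(("decoy", None, f"decoy-{i + 1}"))

    if config.genome_length < 10 * sum(feature_lengths):
        raise PlacementError(
            "genome_length must be at least 10x the planted feature length")

    starts = _place_features(rng, config.genome_length, feature_lengths)

    genome_arr = list(_rand_seq(rng, config.genome_length))
    gff_records = []
    known_catalog, novel_catalog = [], []
    contig = "chr1"
    for (cls, gff_type, name), start, L in zip(feature_meta, starts,
                                               feature_lengths):
        if cls == "decoy":
            region, tag_off = _make_decoy_region(rng, config)
            genome_arr[start:start + L] = list(region)
            truth.decoy_truth.append({
                "name": name,
                "locus": [contig, start, start + L, "+"],
                "tag": region[tag_off:tag_off + config.mature_length],
                "realized_counts": {}})
        elif cls in ("known_mirna", "novel_mirna"):
            mature, prec = _make_precursor(rng, config)
            genome_arr[start:start + L] = list(prec)
            entry = {"name": name, "mature": mature, "precursor": prec,
                     "locus": [contig, start, start + L, "+"],
                     "mature_locus": [contig, start,
                                      start + config.mature_length, "+"]}
            if cls == "known_mirna":
                known_catalog.append(entry)
                gff_records.append((contig, start, start + L, gff_type, name))
            else:
                novel_catalog.append(entry)
        else:
            seq = _rand_clean_seq(rng, L, config)
            genome_arr[start:start + L] = list(seq)
            gff_records.append((contig, start, start + L, gff_type, name))

    genome = {contig: "".join(genome_arr)}
    for entry in known_catalog + novel_catalog:
        truth.mirna_truth[entry["name"]] = {
            "mature": entry["mature"], "precursor": entry["precursor"],
            "locus": entry["locus"], "known": entry in known_catalog,
            "expected_counts": {}, "realized_counts": {}}
    return genome, gff_records, known_catalog, novel_catalog


def write_genome_fasta(genome: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seq_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    seq_write(recs, str(path), "fasta")


def write_gff3(gff_records, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, s0, e0, ftype, name in gff_records:
            fh.write(f"{contig}\tpxmir_sim\t{ftype}\t{s0 + 1}\t{e0}\t.\t+\t.\t"
                     f"ID={name}\n")


def write_catalog_fasta(catalog, mature_path, precursor_path) -> None:
    with open(mature_path, "w") as fh:
        for e in catalog:
            fh.write(f">{e['name']}\n{to_rna(e['mature'])}\n")
    with open(precursor_path, "w") as fh:
        for e in catalog:
            fh.write(f">{e['name']}-precursor\n{to_rna(e['precursor'])}\n")


# ---------------------------------------------------------------------------
# read libraries


def _expected_proportions(config, known_catalog, novel_catalog, rng,
                          truth: GroundTruth):
    """Per-library read-class probabilities; DE fold-changes are exact in
    proportion space (the background class absorbs the difference)."""
    base = {}
    # log-uniform expression so both abundant and near-threshold miRNAs
    # exist; expressed as read proportions anchored at the default depth of
    # 30k reads (2-1500 expected reads there), so any depth stays feasible
    REF = 30_000.0
    lo, hi = 2.0 / REF, 1500.0 / REF
    for i, e in enumerate(known_catalog):
        if i < config.n_de_mirnas:
            base[e["name"]] = config.de_base_proportion
        else:
            base[e["name"]] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    for e in novel_catalog:
        base[e["name"]] = math.exp(
            rng.uniform(math.log(60.0 / REF), math.log(400.0 / REF)))

    other_share = {cls: 0.22 / len(FEATURE_PLAN) for cls in FEATURE_PLAN}

    props = {}
    for lib_idx, lib in enumerate(config.libraries):
        p = {}
        for i, e in enumerate(known_catalog):
            fc = 1.0
            if i < config.n_de_mirnas and lib_idx > 0:
                fc = config.de_fold_changes[i][lib_idx - 1]
            p[e["name"]] = base[e["name"]] * fc
        for e in novel_catalog:
            p[e["name"]] = base[e["name"]]
        for cls, share in other_share.items():
            p[f"class:{cls}"] = share
        for d in truth.decoy_truth:
            p[f"decoy:{d['name']}"] = config.decoy_reads_per_library / 30_000.0
        used = sum(p.values())
        if used >= 0.98:
            raise ValueError("planted proportions leave no background mass")
        p["class:background"] = 1.0 - used
        props[lib] = p
    return props


def _qualities(rng, n: int, *, fail: bool = False) -> str:
    if fail:
        # 30% of bases well below Q20
        n_low = max(1, int(0.3 * n))
        pos = set(map(int, rng.choice(n, size=n_low, replace=False)))
        return "".join(chr(33 + (int(rng.integers(2, 15)) if i in pos
                                 else int(rng.integers(30, 41))))
                       for i in range(n))
    return "".join(chr(33 + int(q)) for q in rng.integers(30, 41, size=n))


def _assemble_read(rng, insert: str, cfg, *, contaminant: bool = False,
                   no_adapter: bool = False) -> str:
    if no_adapter:
        read = insert + _rand_seq(rng, 50 - len(insert))
        while find_adapter3(read, cfg.adapter3) is not None:
            read = insert + _rand_seq(rng, 50 - len(insert))
        return read
    parts = []
    if contaminant:
        parts.append(cfg.adapter5[:12])
    parts.append(insert)
    parts.append(cfg.adapter3)
    parts.append(_rand_seq(rng, 4))
    return "".join(parts)


def _other_insert(rng, locus_seq: str, cfg) -> str:
    """Random clean window from a structural locus, piRNA-leaning length."""
    for _ in range(200):
        L = int(rng.choice(_OTHER_LEN, p=_OTHER_LEN_W))
        if L > len(locus_seq):
            L = len(locus_seq)
        s = int(rng.integers(0, len(locus_seq) - L + 1))
        w = locus_seq[s:s + L]
        if _clean_insert_ok(w, cfg):
            return w
    raise RuntimeError("no clean window in locus")


def generate_read_libraries(config: SimulationConfig, truth: GroundTruth,
                            genome: dict[str, str], gff_records,
                            known_catalog, novel_catalog,
                            ) -> dict[str, list[tuple[str, str, str]]]:
    """Generate raw reads for every library.

    Returns library -> list of (read_id, sequence, quality).  Read ids carry
    the ground-truth class (``lib|class|index``) so every read is
    attributable; exact per-class counts land in ``truth.filter_truth`` and
    ``truth.class_truth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    props = _expected_proportions(config, known_catalog, novel_catalog, rng,
                                  truth)
    by_name = {e["name"]: e for e in known_catalog + novel_catalog}
    # structural-class locus sequences, keyed by class
    locus_seqs: dict[str, list[str]] = {cls: [] for cls in FEATURE_PLAN}
    gfftype_to_cls = {v[2]: k for k, v in FEATURE_PLAN.items()}
    contig = next(iter(genome))
    for c, s0, e0, ftype, _name in gff_records:
        cls = gfftype_to_cls.get(ftype)
        if cls:
            locus_seqs[cls].append(genome[c][s0:e0])

    n_fail = {
        "quality_fail": int(round(config.frac_quality_fail * config.reads_per_library)),
        "no_3adapter": int(round(config.frac_no3adapter * config.reads_per_library)),
        "contaminant_5p": int(round(config.frac_5contaminant * config.reads_per_library)),
        "short": int(round(config.frac_short * config.reads_per_library)),
    }
    n_good = config.reads_per_library - sum(n_fail.values())

    libraries: dict[str, list[tuple[str, str, str]]] = {}
    for lib_idx, lib in enumerate(config.libraries):
        p = props[lib]
        names = sorted(p)
        pvec = np.array([p[n] for n in names])
        pvec = pvec / pvec.sum()
        draws = rng.multinomial(n_good, pvec)
        class_counts = dict(zip(names, (int(d) for d in draws)))

        truth.filter_truth[lib] = dict(n_fail)
        truth.class_truth[lib] = {}
        reads: list[tuple[str, str, str]] = []
        idx = 0

        def emit(insert, label, *, fail_mode=None):
            nonlocal idx
            idx += 1
            if fail_mode == "quality":
                seq = _assemble_read(rng, insert, config)
                qual = _qualities(rng, len(seq), fail=True)
            elif fail_mode == "contaminant":
                seq = _assemble_read(rng, insert, config, contaminant=True)
                qual = _qualities(rng, len(seq))
            elif fail_mode == "no_adapter":
                seq = _assemble_read(rng, insert, config, no_adapter=True)
                qual = _qualities(rng, len(seq))
            else:
                seq = _assemble_read(rng, insert, config)
                qual = _qualities(rng, len(seq))
            reads.append((f"{lib}|{label}|{idx}", seq, qual))

        # planted failures (count ledgered per failure class)
        for _ in range(n_fail["quality_fail"]):
            emit(_rand_clean_seq(rng, 22, config), "fail_quality",
                 fail_mode="quality")
        for _ in range(n_fail["contaminant_5p"]):
            emit(_rand_clean_seq(rng, 22, config), "fail_contaminant",
                 fail_mode="contaminant")
        for _ in range(n_fail["no_3adapter"]):
            emit(_rand_clean_seq(rng, 22, config), "fail_no_adapter",
                 fail_mode="no_adapter")
        for _ in range(n_fail["short"]):
            L = int(rng.integers(10, 18))
            emit(_rand_clean_seq(rng, L, config), "fail_short")

        # good reads, class by class
        decoy_by_name = {d["name"]: d for d in truth.decoy_truth}
        for name in names:
            cnt = class_counts[name]
            if name.startswith("decoy:"):
                d = decoy_by_name[name.split(":", 1)[1]]
                d["realized_counts"][lib] = cnt
                for _ in range(cnt):
                    emit(d["tag"], d["name"])
            elif name.startswith("class:"):
                cls = name.split(":", 1)[1]
                truth.class_truth[lib][cls] = cnt
                for _ in range(cnt):
                    if cls == "background":
                        insert = _background_insert(rng, genome[contig],
                                                    gff_records, config)
                    else:
                        locus = locus_seqs[cls][int(rng.integers(len(locus_seqs[cls])))]
                        insert = _other_insert(rng, locus, config)
                    emit(insert, cls)
            else:
                entry = by_name[name]
                truth.mirna_truth[name]["expected_counts"][lib] = (
                    float(n_good * pvec[names.index(name)]))
                truth.mirna_truth[name]["realized_counts"][lib] = cnt
                mature = entry["mature"]
                for _ in range(cnt):
                    # 15% 3'-trimmed isomiRs, still mapping within the locus
                    insert = mature[:-1] if rng.random() < 0.15 else mature
                    emit(insert, name)

        order = rng.permutation(len(reads))
        libraries[lib] = [reads[i] for i in order]

    for i in range(config.n_de_mirnas):
        name = known_catalog[i]["name"]
        truth.de_truth[name] = {
            trt: math.log2(config.de_fold_changes[i][j])
            for j, trt in enumerate(config.treatments)}
    return libraries


def _background_insert(rng, chrom: str, gff_records, config) -> str:
    """A clean window from the genome outside every annotated feature."""
    spans = sorted((s0, e0) for _c, s0, e0, _t, _n in gff_records)
    for _ in range(500):
        L = int(rng.choice(_OTHER_LEN, p=_OTHER_LEN_W))
        s = int(rng.integers(0, len(chrom) - L + 1))
        if any(s < e0 and s0 < s + L for s0, e0 in spans):
            continue
        w = chrom[s:s + L]
        if _clean_insert_ok(w, config):
            return w
    raise RuntimeError("could not draw a background insert")


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# transcriptome with planted target sites


def generate_transcriptome_with_sites(config: SimulationConfig,
                                      truth: GroundTruth, known_catalog,
                                      ) -> dict[str, str]:
    """3'-UTR set: strong planted sites for DE miRNAs, seed-only weak sites
    on some decoys, clean decoys otherwise.  Intervals are 0-based
    half-open; every planted site lies within its UTR."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    de = known_catalog[:config.n_de_mirnas]
    n_strong = config.n_de_mirnas * config.planted_sites_per_de_mirna
    if n_strong > config.n_utrs:
        raise ValueError("not enough UTRs for the planted sites")
    if config.utr_length < config.mature_length + 20:
        raise PlacementError("UTR too short for a planted site")

    utrs: dict[str, str] = {}
    # exclude even the 6-mer seed core so decoy UTRs cannot fire a seed call
    seed_seqs = {e["name"]: e["mature"][1:7] for e in de}

    def free_of_seeds(seq: str) -> bool:
        return not any(revcomp(s) in seq for s in seed_seqs.values())

    uid = 0
    for e in de:
        mature = e["mature"]
        strong_site = revcomp(mature[1:]) + "A"  # full 3' pairing + 8mer seed
        for _k in range(config.planted_sites_per_de_mirna):
            uid += 1
            name = f"utr-{uid:03d}"
            while True:
                seq = _rand_seq(rng, config.utr_length)
                pos = int(rng.integers(10, config.utr_length
                                       - len(strong_site) - 10))
                seq = seq[:pos] + strong_site + seq[pos + len(strong_site):]
                if free_of_seeds(seq[:pos]) and free_of_seeds(
                        seq[pos + len(strong_site):]):
                    break
            utrs[name] = seq
            truth.site_truth.append({
                "mirna": e["name"], "utr": name,
                "start": pos, "end": pos + len(strong_site),
                "site_type": "strong_8mer"})

    # bases that can pair a given miRNA base (WC or G:U wobble), DNA letters
    pairs_with = {"A": "T", "C": "G", "G": "CT", "T": "AG"}

    n_weak = min(len(de), (config.n_utrs - uid) // 3)
    for i in range(n_weak):
        uid += 1
        name = f"utr-{uid:03d}"
        e = de[i % len(de)]
        mature = e["mature"]
        weak = revcomp(mature[1:8]) + "A"  # seed only, no 3' pairing
        while True:
            seq = _rand_seq(rng, config.utr_length)
            pos = int(rng.integers(20, config.utr_length - len(weak) - 10))
            # kill 3'-supplementary pairing: the flank 5' of the seed match
            # (which would face miRNA positions 9..) gets non-pairing bases
            dead = []
            for k in range(1, 15):
                mi = 7 + k
                forbidden = pairs_with[mature[mi]] if mi < len(mature) else ""
                choices = [b for b in "ACGT" if b not in forbidden]
                dead.append(choices[int(rng.integers(len(choices)))])
            seq = (seq[:pos - 14] + "".join(reversed(dead)) + weak
                   + seq[pos + len(weak):])
            if free_of_seeds(seq[:pos]) and free_of_seeds(seq[pos + len(weak):]):
                break
        utrs[name] = seq
        truth.site_truth.append({
            "mirna": e["name"], "utr": name, "start": pos,
            "end": pos + len(weak), "site_type": "weak_seed_only"})

    while uid < config.n_utrs:
        uid += 1
        name = f"utr-{uid:03d}"
        while True:
            seq = _rand_seq(rng, config.utr_length)
            if free_of_seeds(seq):
                break
        utrs[name] = seq

    truth.utr_sequences = dict(utrs)
    return utrs


def write_utr_fasta(utrs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in utrs.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# term maps


GO_CATEGORIES = ["biological_process", "cellular_component",
                 "molecular_function"]


def generate_term_maps(config: SimulationConfig, truth: GroundTruth,
                       ) -> list[tuple[str, str, str, str]]:
    """Gene->term rows (gene_id, term_id, term_name, category).

    Genes are the UTR ids; genes carrying planted strong sites are heavily
    annotated with two planted terms (one GO-like, one pathway-like) that a
    correct enrichment stage must recover.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genes = [f"utr-{i + 1:03d}" for i in range(config.n_utrs)]
    target_genes = sorted({s["utr"] for s in truth.site_truth
                           if s["site_type"] == "strong_8mer"})
    rows = []
    planted = [("GO:9000001", "planted response process", "biological_process"),
               ("PATH:900001", "planted response pathway", "pathway")]
    for term_id, term_name, cat in planted:
        for g in genes:
            p = 0.85 if g in target_genes else 0.08
            if rng.random() < p:
                rows.append((g, term_id, term_name, cat))
    n_background_terms = 18
    for t in range(n_background_terms):
        cat = (GO_CATEGORIES[t % 3] if t < 12 else "pathway")
        term_id = (f"GO:80000{t:02d}" if cat != "pathway" else f"PATH:8000{t:02d}")
        for g in genes:
            if rng.random() < 0.15:
                rows.append((g, term_id, f"background term {t}", cat))
    truth.term_truth = [p[0] for p in planted]
    return rows


def write_term_map(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\tterm_name\tcategory\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


# ---------------------------------------------------------------------------
# qPCR table


def generate_qpcr_table(config: SimulationConfig, truth: GroundTruth,
                        ) -> list[dict]:
    """Ct rows for every DE miRNA: 3 replicates x all groups.

    target Ct = baseline - log2(true relative expression) + noise;
    reference (U6-style) Ct constant + noise, so 2^-ddCt recovers the
    planted fold-change.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    rows = []
    baseline_ct, ref_ct = 25.0, 15.0
    for name, fc_by_trt in truth.de_truth.items():
        truth.qpcr_true_rq[name] = {config.control: 1.0}
        for trt, lfc in fc_by_trt.items():
            truth.qpcr_true_rq[name][trt] = 2.0 ** lfc
        for group in config.libraries:
            rel = truth.qpcr_true_rq[name][group]
            for rep in range(1, config.qpcr_replicates + 1):
                ct_t = (baseline_ct - math.log2(rel)
                        + rng.normal(0, config.qpcr_noise_sd))
                ct_r = ref_ct + rng.normal(0, config.qpcr_noise_sd)
                rows.append({"target": name, "group": group,
                             "replicate": rep,
                             "ct_target": round(ct_t, 4),
                             "ct_reference": round(ct_r, 4)})
    return rows


def write_qpcr_table(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tgroup\treplicate\tct_target\tct_reference\n")
        for r in rows:
            fh.write(f"{r['target']}\t{r['group']}\t{r['replicate']}\t"
                     f"{r['ct_target']}\t{r['ct_reference']}\n")


# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    truth: GroundTruth
    genome: dict[str, str]
    gff_records: list
    known_catalog: list
    novel_catalog: list
    libraries: dict[str, list[tuple[str, str, str]]]
    utrs: dict[str, str]
    term_rows: list
    qpcr_rows: list


def generate_all(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage and return the full in-memory study."""
    truth = GroundTruth()
    genome, gff, known, novel = generate_genome(config, truth)
    libs = generate_read_libraries(config, truth, genome, gff, known, novel)
    utrs = generate_transcriptome_with_sites(config, truth, known)
    terms = generate_term_maps(config, truth)
    qpcr = generate_qpcr_table(config, truth)
    return SyntheticStudy(config, truth, genome, gff, known, novel,
                          libs, utrs, terms, qpcr)
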