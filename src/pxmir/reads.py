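"""Raw-read cleaning, tag collapsing, genome mapping and annotation.

The cleaning cascade applies, in order: low-quality removal, 5' primer
contaminant removal, 3' adapter location (reads without a locatable adapter
or with an empty insert are dropped), and the insert-length filter
(18-30 nt).  Each removed read increments exactly one counter — the first
failing filter wins — so raw_total = clean_total + sum(removed_*) always.

Mapping is exact and full-length on both strands (an enumerable matcher in
place of a seed-and-extend aligner); annotation follows the class priority
rRNA > tRNA > snRNA > snoRNA > scRNA > known miRNA > repeat > exon >
intron, with >= 1 nt of overlap and unannotated as the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import DNA_ALPHABET, revcomp

__all__ = [
    "RawRead",
    "CleanTag",
    "LibraryStats",
    "ANNOTATION_PRIORITY",
    "clean_reads",
    "clean_fastq",
    "collapse_tags",
    "length_distribution",
    "map_tags",
    "annotate_tags",
    "find_adapter3",
    "is_low_quality",
    "has_5prime_contaminant",
    "contains_internal_adapter",
]

MIN_INSERT = 18
MAX_INSERT = 30
QUALITY_PHRED_MIN = 20      # a base below this counts as low quality
QUALITY_FRAC_MAX = 0.20     # >20% low-quality bases fails the read
ADAPTER3_MIN_MATCH = 6      # minimum adapter-prefix match length
ADAPTER3_MAX_MISMATCH = 1
ADAPTER5_MIN_MATCH = 8      # exact 5'-adapter prefix marking a contaminant

#: highest priority first; GenBank/Rfam structural classes outrank miRNA
ANNOTATION_PRIORITY = [
    "rRNA", "tRNA", "snRNA", "snoRNA", "scRNA",
    "known_miRNA", "repeat", "exon", "intron",
]
_RANK = {c: i for i, c in enumerate(ANNOTATION_PRIORITY)}

#: GFF3 feature type -> annotation class
GFF_TYPE_MAP = {
    "rRNA": "rRNA", "tRNA": "tRNA", "snRNA": "snRNA", "snoRNA": "snoRNA",
    "scRNA": "scRNA",
    "miRNA_primary_transcript": "known_miRNA", "pre_miRNA": "known_miRNA",
    "miRNA": "known_miRNA",
    "repeat_region": "repeat", "dispersed_repeat": "repeat",
    "exon": "exon", "intron": "intron",
}


@dataclass
class RawRead:
    id: str
    sequence: str
    quality: str
    library: str = ""

    def validate(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"record {self.id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.quality)})")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id}: bad characters {sorted(bad)}")


@dataclass
class CleanTag:
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibraryStats:
    library: str
    raw_total: int = 0
    removed_low_quality: int = 0
    removed_5prime_contaminant: int = 0
    removed_no_3adapter_or_insert: int = 0
    removed_short: int = 0
    clean_total: int = 0
    mapped_total: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        removed = (self.removed_low_quality + self.removed_5prime_contaminant
                   + self.removed_no_3adapter_or_insert + self.removed_short)
        assert self.clean_total == self.raw_total - removed
        assert sum(self.length_histogram.values()) == self.clean_total


def is_low_quality(quality: str, *, phred_min: int = QUALITY_PHRED_MIN,
                   frac_max: float = QUALITY_FRAC_MAX) -> bool:
    if not quality:
        return True
    low = sum(1 for c in quality if ord(c) - 33 < phred_min)
    return low / len(quality) > frac_max


def has_5prime_contaminant(sequence: str, adapter5: str,
                           min_match: int = ADAPTER5_MIN_MATCH) -> bool:
    if len(adapter5) < min_match:
        return False
    return sequence.startswith(adapter5[:min_match])


def find_adapter3(sequence: str, adapter3: str,
                  *, min_match: int = ADAPTER3_MIN_MATCH,
                  max_mismatch: int = ADAPTER3_MAX_MISMATCH) -> int | None:
    """Return the start of the 3' adapter, scanning 5'->3'; None if absent.

    A position qualifies when >= ``min_match`` nt of the adapter prefix align
    there with at most ``max_mismatch`` mismatches.
    """
    n, m = len(sequence), len(adapter3)
    for i in range(0, n - min_match + 1):
        span = min(m, n - i)
        mism = 0
        for a, b in zip(sequence[i:i + span], adapter3[:span]):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return None


def contains_internal_adapter(insert: str, adapter3: str) -> bool:
    """True if the cleaner would trim inside this insert (used by the
    generator to plant unambiguous reads)."""
    return find_adapter3(insert, adapter3) is not None


def clean_reads(reads, adapter3: str, adapter5: str,
                *, min_len: int = MIN_INSERT, max_len: int = MAX_INSERT,
                library: str = "") -> tuple[list[str], LibraryStats]:
    """Run the filter cascade; returns (clean inserts, LibraryStats)."""
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    stats = LibraryStats(library=library)
    inserts: list[str] = []
    for read in reads:
        read.validate()
        stats.raw_total += 1
        if is_low_quality(read.quality):
            stats.removed_low_quality += 1
            continue
        seq = read.sequence.upper()
        if has_5prime_contaminant(seq, adapter5):
            stats.removed_5prime_contaminant += 1
            continue
        pos = find_adapter3(seq, adapter3)
        if pos is None or pos == 0:
            stats.removed_no_3adapter_or_insert += 1
            continue
        insert = seq[:pos]
        if not (min_len <= len(insert) <= max_len):
            stats.removed_short += 1
            continue
        inserts.append(insert)
        stats.clean_total += 1
        stats.length_histogram[len(insert)] = \
            stats.length_histogram.get(len(insert), 0) + 1
    stats.check()
    return inserts, stats


def read_fastq(path, library: str = ""):
    """Yield RawRead records from a Phred+33 FASTQ file."""
    with open(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(rid, seq, qual, library)


def clean_fastq(path, adapter3: str, adapter5: str, library: str = "",
                **kw) -> tuple[list[str], LibraryStats]:
    return clean_reads(read_fastq(path, library), adapter3, adapter5,
                       library=library, **kw)


def collapse_tags(inserts_by_library: dict[str, list[str]]) -> list[CleanTag]:
    """Collapse inserts to unique tags with per-library counts.

    Ordered by descending total count, then lexicographically.
    """
    tags: dict[str, dict[str, int]] = {}
    for lib, inserts in inserts_by_library.items():
        for s in inserts:
            d = tags.setdefault(s, {})
            d[lib] = d.get(lib, 0) + 1
    out = [CleanTag(seq, counts) for seq, counts in tags.items()]
    out.sort(key=lambda t: (-t.total, t.sequence))
    return out


def length_distribution(tags: list[CleanTag]) -> dict[str, dict[int, float]]:
    """Per-library read-weighted length frequencies (sum to 1 per library)."""
    counts: dict[str, dict[int, int]] = {}
    for tag in tags:
        L = len(tag.sequence)
        for lib, c in tag.counts.items():
            d = counts.setdefault(lib, {})
            d[L] = d.get(L, 0) + c
    out = {}
    for lib, d in counts.items():
        total = sum(d.values())
        out[lib] = {L: c / total for L, c in sorted(d.items())}
    return out


def map_tags(tags: list[CleanTag], genome: dict[str, str],
             ) -> dict[str, list[tuple[str, int, int, str]]]:
    """Exact full-length mapping of tags to both genome strands.

    Returns tag sequence -> list of (contig, start, end, strand) hits with
    0-based half-open coordinates on the forward strand.  Unmapped tags get
    an empty list.
    """
    K = 18  # tags are >= 18 nt, so an 18-mer prefix index finds every hit
    hits: dict[str, list[tuple[str, int, int, str]]] = {t.sequence: [] for t in tags}
    for contig, seq in genome.items():
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - K + 1):
            index.setdefault(seq[i:i + K], []).append(i)
        for tag in tags:
            q = tag.sequence
            L = len(q)
            for query, strand in ((q, "+"), (revcomp(q), "-")):
                if L < K:
                    start = seq.find(query)
                    while start != -1:
                        hits[q].append((contig, start, start + L, strand))
                        start = seq.find(query, start + 1)
                    continue
                for pos in index.get(query[:K], ()):
                    if seq.startswith(query, pos):
                        hits[q].append((contig, pos, pos + L, strand))
    for h in hits.values():
        h.sort()
    return hits


def mapped_read_total(tags: list[CleanTag], hits, library: str) -> int:
    return sum(t.counts.get(library, 0) for t in tags if hits.get(t.sequence))


def parse_gff3(path) -> list[tuple[str, int, int, str]]:
    """Read GFF3 features as (contig, start0, end0, class), converting the
    1-based inclusive convention to 0-based half-open; feature types outside
    the class map are ignored."""
    from gffutils.iterators import DataIterator

    feats = []
    try:
        for f in DataIterator(str(path)):
            if f.featuretype in GFF_TYPE_MAP:
                feats.append((f.seqid, f.start - 1, f.end,
                              GFF_TYPE_MAP[f.featuretype]))
    except Exception as exc:
        raise ValueError(f"malformed GFF3 in {path}: {exc}") from exc
    return feats


def annotate_tags(tags: list[CleanTag], hits,
                  features: list[tuple[str, int, int, str]],
                  ) -> dict[str, str]:
    """Assign each tag the highest-priority class among features overlapping
    any of its hits (>= 1 nt); tags without hits or overlaps are unannotated."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for contig, s, e, cls in features:
        if e > s:
            trees.setdefault(contig, IntervalTree()).addi(s, e, cls)

    out: dict[str, str] = {}
    for tag in tags:
        best = None
        for contig, s, e, _strand in hits.get(tag.sequence, []):
            tree = trees.get(contig)
            if tree is None:
                continue
            for iv in tree.overlap(s, e):
                r = _RANK[iv.data]
                if best is None or r < best:
                    best = r
        out[tag.sequence] = ANNOTATION_PRIORITY[best] if best is not None else "unannotated"
    return out
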