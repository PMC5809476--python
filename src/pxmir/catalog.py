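"""Known-miRNA identification and novel-miRNA discovery from clean tags.

Known miRNAs are quantified by matching collapsed tags against a mature
catalog with a fixed 5' end (the seed-defining end) and up to 2 nt of 3'
isomiR variation, then filtered by the minimum-abundance rule (raw count
>= 10 in at least one library).

Novel candidates are hairpins excised around unannotated genome-mapped
tags, folded with the simplified energy model, scored with a documented
simplified score (``simplified_score``: log2 tag count plus a star-arm
pairing bonus — not the miRDeep2 Bayesian model), and screened with a
dinucleotide-shuffle randomization test.  Acceptance requires
score > 1, shuffle p < 0.05 and MFE < -19 kcal/mol, all strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, to_dna, to_rna
from .fold import fold

__all__ = [
    "MatureMiRNA",
    "HairpinCandidate",
    "ExpressionRecord",
    "match_known",
    "filter_low_count",
    "fold_hairpin",
    "dinucleotide_shuffle",
    "randfold_test",
    "discover_novel",
    "filter_novel",
]

KNOWN_MIN_COUNT = 10
NOVEL_SCORE_MIN = 1.0
NOVEL_RANDFOLD_ALPHA = 0.05
NOVEL_MFE_MAX = -19.0
FIVE_PRIME_EXACT = 18   # nt of the 5' end that must match exactly
THREE_PRIME_TOL = 2     # nt of allowed 3' length variation (isomiRs)


@dataclass
class MatureMiRNA:
    name: str
    sequence: str
    precursor_name: str | None = None
    arm: str = "unknown"  # 5p | 3p | unknown


@dataclass
class HairpinCandidate:
    """A putative novel-miRNA hairpin around an unannotated tag locus."""

    name: str
    locus: tuple[str, int, int, str]      # (contig, start, end, strand)
    sequence: str
    structure: str
    mfe: float
    simplified_score: float
    randfold_p: float
    mature_arm: tuple[int, int]           # interval of the tag within sequence
    tag_sequence: str = ""
    tag_count: int = 0


@dataclass
class ExpressionRecord:
    mirna: str
    raw_counts: dict[str, int] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)


def match_known(tags, catalog: list[MatureMiRNA]) -> list[ExpressionRecord]:
    """Assign collapsed tags to mature miRNAs and sum counts.

    A tag matches a mature sequence when their first 18 nt are identical,
    the shorter of the two is a prefix of the longer, and the length
    difference is at most 2 nt (3' isomiRs).  Each tag goes to at most one
    miRNA: the one with the longest exact shared prefix, ties broken by
    lexicographically first name.

    ``tags`` is an iterable of objects with ``sequence`` and ``counts``
    attributes (see :class:`pxmir.reads.CleanTag`).
    """
    names = [m.name for m in catalog]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate catalog names: {dup}")

    by_prefix: dict[str, list[MatureMiRNA]] = {}
    for m in catalog:
        seq = to_dna(m.sequence)
        by_prefix.setdefault(seq[:FIVE_PRIME_EXACT], []).append(m)

    records: dict[str, ExpressionRecord] = {
        m.name: ExpressionRecord(m.name) for m in catalog}
    for tag in tags:
        seq = to_dna(tag.sequence)
        cands = []
        for m in by_prefix.get(seq[:FIVE_PRIME_EXACT], []):
            mseq = to_dna(m.sequence)
            if abs(len(seq) - len(mseq)) > THREE_PRIME_TOL:
                continue
            short = min(len(seq), len(mseq))
            if seq[:short] != mseq[:short]:
                continue
            cands.append((short, m.name))
        if not cands:
            continue
        cands.sort(key=lambda t: (-t[0], t[1]))
        rec = records[cands[0][1]]
        for lib, c in tag.counts.items():
            rec.raw_counts[lib] = rec.raw_counts.get(lib, 0) + c
    return [r for r in records.values() if r.raw_counts]


def filter_low_count(records: list[ExpressionRecord],
                     min_count: int = KNOWN_MIN_COUNT) -> list[ExpressionRecord]:
    """Keep records with raw count >= ``min_count`` in at least one library."""
    return [r for r in records
            if r.raw_counts and max(r.raw_counts.values()) >= min_count]


def fold_hairpin(sequence: str) -> tuple[str, float]:
    """Fold a precursor-scale sequence (20-200 nt); see :func:`pxmir.fold.fold`."""
    if not 20 <= len(sequence) <= 200:
        raise ValueError(f"hairpin length {len(sequence)} outside [20, 200]")
    return fold(sequence)


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide composition.

    Altschul–Erickson Euler-path shuffle on the dinucleotide transition
    multigraph: the last outgoing edge of every vertex other than the final
    nucleotide is chosen to form an arborescence into the final vertex, the
    remaining edges are permuted uniformly, and the walk is read off.
    """
    s = to_dna(sequence)
    if len(s) < 4:
        raise ValueError("sequence too short to shuffle (<4 nt)")
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges)
    last = s[-1]

    for _ in range(100):
        # sample a candidate last-edge per vertex; accept if they form a tree
        # that can reach the final vertex (Wilson-style rejection is simplest
        # and fast at this alphabet size)
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen, cur = {v}, v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        out_edges = {}
        for v in vertices:
            pool = list(edges[v])
            if v in last_edge:
                pool.remove(last_edge[v])
            rng.shuffle(pool)
            if v in last_edge:
                pool.append(last_edge[v])
            out_edges[v] = pool
        chars = [s[0]]
        cur = s[0]
        idx = {v: 0 for v in vertices}
        for _step in range(len(s) - 1):
            nxt = out_edges[cur][idx[cur]]
            idx[cur] += 1
            chars.append(nxt)
            cur = nxt
        return "".join(chars)
    # degenerate composition (e.g. homopolymer): identity is the only walk
    return s


def randfold_test(sequence: str, n_shuffles: int = 999,
                  seed: int | np.random.Generator = 0) -> float:
    """Empirical MFE p-value against dinucleotide-preserving shuffles.

    p = (1 + #{shuffles with MFE <= observed}) / (1 + n_shuffles), so the
    smallest attainable value is 1/(n_shuffles + 1).
    """
    if n_shuffles < 99:
        raise ValueError("n_shuffles must be >= 99")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    _, observed = fold(sequence)
    hits = 0
    for _ in range(n_shuffles):
        _, e = fold(dinucleotide_shuffle(sequence, rng))
        if e <= observed:
            hits += 1
    return (1 + hits) / (1 + n_shuffles)


FLANK = 70       # nt of genomic flank on the far side of the tag
NEAR_FLANK = 10  # nt on the near side, so the arm sits inside the stem
STAR_PAIR_FRAC = 0.6


def _excise(genome: dict[str, str], contig: str, start: int, end: int,
            strand: str) -> str | None:
    seq = genome[contig]
    if start < 0 or end > len(seq):
        return None
    sub = seq[start:end]
    return revcomp(sub) if strand == "-" else sub


def discover_novel(tags, hits: dict[str, list[tuple[str, int, int, str]]],
                   genome: dict[str, str], *, n_shuffles: int = 199,
                   seed: int = 0, min_count: int = 10,
                   lazy_shuffle: bool = False,
                   ) -> list[HairpinCandidate]:
    """Build hairpin candidates around unannotated mapped tags.

    Tags below ``min_count`` total reads are not considered (sequencing
    noise; also keeps the fold/shuffle work proportional to the signal),
    and tags stacking on an already-candidate locus (isomiRs of the same
    arm) are collapsed into it.  For each remaining tag's first genomic
    hit, two excisions are folded — tag as the putative 5p arm (long 3'
    flank) and as the 3p arm (long 5' flank) — and the lower-MFE one is
    kept.  simplified_score = log2(total tag count) plus 1 if >= 60% of
    the tag's positions are base-paired in the chosen structure (a star
    arm exists), else minus 1.

    With ``lazy_shuffle`` the randomization test runs only for candidates
    that already satisfy the score and MFE criteria; skipped candidates
    report randfold_p = 1.0 (no evidence of non-random stability).  The
    accepted set after :func:`filter_novel` is identical either way.
    """
    rng = np.random.default_rng(seed)
    out: list[HairpinCandidate] = []
    ordered = sorted(tags, key=lambda t: (-sum(t.counts.values()), t.sequence))
    taken: list[tuple[str, int, int]] = []   # candidate loci already built
    for i, tag in enumerate(ordered):
        if sum(tag.counts.values()) < min_count:
            continue
        tag_hits = hits.get(tag.sequence, [])
        if not tag_hits:
            continue
        c0, s0, e0, _ = tag_hits[0]
        if any(c == c0 and s0 < e and s < e0 for c, s, e in taken):
            continue
        taken.append((c0, s0, e0))
        contig, start, end, strand = tag_hits[0]
        L = len(tag.sequence)
        if strand == "+":
            exc5 = (start - NEAR_FLANK, end + FLANK)   # tag near 5' end
            exc3 = (start - FLANK, end + NEAR_FLANK)   # tag near 3' end
        else:
            exc5 = (start - FLANK, end + NEAR_FLANK)
            exc3 = (start - NEAR_FLANK, end + FLANK)
        best = None
        for (a, b), arm in ((exc5, "5p"), (exc3, "3p")):
            seq = _excise(genome, contig, a, b, strand)
            if seq is None:
                continue
            db, mfe = fold(seq)
            if best is None or mfe < best[1]:
                if arm == "5p":
                    arm_iv = (NEAR_FLANK, NEAR_FLANK + L)
                else:
                    arm_iv = (FLANK, FLANK + L)
                best = (db, mfe, seq, arm_iv)
        if best is None:
            continue  # locus too near a contig edge
        db, mfe, seq, (a0, a1) = best
        total = sum(tag.counts.values())
        paired = sum(1 for p in range(a0, a1) if db[p] != ".")
        score = math.log2(total) + (1.0 if paired >= STAR_PAIR_FRAC * L else -1.0)
        if lazy_shuffle and not (score > NOVEL_SCORE_MIN and mfe < NOVEL_MFE_MAX):
            p = 1.0
        else:
            p = randfold_test(seq, n_shuffles=n_shuffles, seed=rng)
        out.append(HairpinCandidate(
            name=f"novel-cand-{i + 1}",
            locus=(contig, start, end, strand),
            sequence=to_rna(seq), structure=db, mfe=mfe,
            simplified_score=score, randfold_p=p,
            mature_arm=(a0, a1), tag_sequence=tag.sequence, tag_count=total))
    return out


def filter_novel(candidates: list[HairpinCandidate], *,
                 score_min: float = NOVEL_SCORE_MIN,
                 alpha: float = NOVEL_RANDFOLD_ALPHA,
                 mfe_max: float = NOVEL_MFE_MAX) -> list[HairpinCandidate]:
    """Accept candidates with score > 1, shuffle p < 0.05 and MFE < -19
    kcal/mol — every inequality strict."""
    return [c for c in candidates
            if c.simplified_score > score_min
            and c.randfold_p < alpha
            and c.mfe < mfe_max]
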