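"""miRNA target-site prediction on 3'-UTRs with three independent predictors.

Three deliberately different lines of evidence, mirroring the common
practice of intersecting a seed-based, an alignment-based and a
hybridization-energy-based tool:

* :func:`seed_scan` — canonical seed-site types (8mer, 7mer-m8, 7mer-A1,
  6mer) by exact match to the reverse complement of miRNA positions 2-8.
* :func:`align_scan` — position-weighted local complementarity alignment
  (Watson-Crick +5, G:U +1, mismatch -4, gap open -8 / extend -2, seed
  positions doubled).
* :func:`duplex_scan` — intermolecular duplex energy by dynamic programming
  with the shared nearest-neighbor stack table and per-nucleotide bulge
  penalties (no intramolecular structure).

Only sites called by all three predictors are consensus
(:func:`consensus_intersect`), which also reports pairwise/triple Venn
counts over merged "spots" (interval-overlap clusters per miRNA and
transcript).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, to_dna
from .fold import STACK_ENERGY

__all__ = [
    "TargetSite",
    "seed_scan",
    "align_scan",
    "duplex_scan",
    "consensus_intersect",
]

ALIGN_THRESHOLD = 80.0
DUPLEX_THRESHOLD = -20.0
SEED_MIN_TYPE = "7mer"   # report >= 7mer by default

MATCH_WC = 5
MATCH_GU = 1
MISMATCH = -4
GAP_OPEN = -8
GAP_EXTEND = -2
SEED_POSITIONS = range(1, 8)       # miRNA indices 1..7 = positions 2..8
BULGE_PENALTY = 20                 # tenths of kcal/mol per unpaired nt
MAX_BULGE = 3                      # max unpaired nts between paired neighbors

_SITE_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1, "none": 0}


@dataclass
class TargetSite:
    mirna: str
    transcript: str
    interval: tuple[int, int]     # 0-based half-open on the transcript
    site_type: str = "none"
    align_score: float = 0.0
    duplex_energy: float = 0.0
    predictors_hit: frozenset = field(default_factory=frozenset)
    consensus: bool = False


def seed_scan(mirna_name: str, mirna_seq: str, utr_name: str, utr_seq: str,
              *, min_type: str = SEED_MIN_TYPE) -> list[TargetSite]:
    """Canonical seed sites on the UTR.

    For a match of the reverse complement of miRNA positions 2-7 at UTR
    position i, position i-1 pairing miRNA position 8 upgrades to 7mer-m8,
    an A at position i+6 (opposite position 1) upgrades to 7mer-A1, and
    both make an 8mer.
    """
    m = to_dna(mirna_seq)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    u = to_dna(utr_seq)
    core6 = revcomp(m[1:7])
    m8_base = revcomp(m[7])          # UTR base pairing miRNA position 8
    min_rank = {"6mer": 1, "7mer": 2, "8mer": 4}[min_type]
    sites = []
    i = u.find(core6)
    while i != -1:
        has_m8 = i >= 1 and u[i - 1] == m8_base
        has_a1 = i + 6 < len(u) and u[i + 6] == "A"
        if has_m8 and has_a1:
            stype, iv = "8mer", (i - 1, i + 7)
        elif has_m8:
            stype, iv = "7mer-m8", (i - 1, i + 6)
        elif has_a1:
            stype, iv = "7mer-A1", (i, i + 7)
        else:
            stype, iv = "6mer", (i, i + 6)
        if _SITE_RANK[stype] >= min_rank:
            sites.append(TargetSite(mirna_name, utr_name, iv, site_type=stype,
                                    predictors_hit=frozenset({"seed"})))
        i = u.find(core6, i + 1)
    return sites


def _align_matrices(mir: str, utr: str):
    """Score matrix for local alignment of the miRNA's reverse complement
    against the UTR, with seed columns doubled."""
    rc = revcomp(mir)
    L = len(rc)
    # miRNA index represented by rc column j is L-1-j
    weights = np.array([2.0 if (L - 1 - j) in SEED_POSITIONS else 1.0
                        for j in range(L)])
    sub = np.empty((len(utr), L))
    for j, c in enumerate(rc):
        for i, v in enumerate(utr):
            if v == c:
                s = MATCH_WC
            elif (c == "C" and v == "T") or (c == "A" and v == "G"):
                s = MATCH_GU   # G:U wobble against the miRNA base
            else:
                s = MISMATCH
            sub[i, j] = s * weights[j]
    return rc, weights, sub


def _smith_waterman(sub: np.ndarray, weights: np.ndarray,
                    masked: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Local alignment with affine gaps; returns (best score, UTR interval)."""
    n, L = sub.shape
    NEG = -1e9
    H = np.zeros((n + 1, L + 1))
    Eg = np.full((n + 1, L + 1), NEG)   # gap in miRNA (UTR consumed)
    Fg = np.full((n + 1, L + 1), NEG)   # gap in UTR
    start = np.zeros((n + 1, L + 1), dtype=int)  # UTR start of local path
    start[:, 0] = np.arange(n + 1)  # empty path "ending" at row i starts there
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        row_masked = masked[i - 1]
        for j in range(1, L + 1):
            gw = weights[j - 1]
            e = max(H[i - 1][j] + GAP_OPEN * gw, Eg[i - 1][j] + GAP_EXTEND * gw)
            f = max(H[i][j - 1] + GAP_OPEN * gw, Fg[i][j - 1] + GAP_EXTEND * gw)
            diag = H[i - 1][j - 1] + (NEG if row_masked else sub[i - 1, j - 1])
            h = max(0.0, diag, e, f)
            H[i][j], Eg[i][j], Fg[i][j] = h, e, f
            if h == 0.0:
                start[i][j] = i
            elif h == diag:
                start[i][j] = start[i - 1][j - 1]
            elif h == e:
                start[i][j] = start[i - 1][j]
            else:
                start[i][j] = start[i][j - 1]
            if h > best:
                best, best_pos = h, (i, j)
    if best_pos is None:
        return 0.0, (0, 0)
    i, j = best_pos
    return best, (start[i][j], i)


def align_scan(mirna_name: str, mirna_seq: str, utr_name: str, utr_seq: str,
               *, threshold: float = ALIGN_THRESHOLD) -> list[TargetSite]:
    """Greedy best-first extraction of non-overlapping local alignments
    scoring at least ``threshold``."""
    mir, utr = to_dna(mirna_seq), to_dna(utr_seq)
    _rc, weights, sub = _align_matrices(mir, utr)
    masked = np.zeros(len(utr), dtype=bool)
    sites = []
    while True:
        score, (s, e) = _smith_waterman(sub, weights, masked)
        if score < threshold or e <= s:
            break
        sites.append(TargetSite(mirna_name, utr_name, (int(s), int(e)),
                                align_score=float(score),
                                predictors_hit=frozenset({"align"})))
        masked[s:e] = True
    sites.sort(key=lambda t: t.interval)
    return sites


_RNA = str.maketrans("T", "U")


def _pair_key(u_base: str, m_base: str) -> str | None:
    k = (u_base + m_base).translate(_RNA)
    return k if k in STACK_ENERGY else None


def duplex_energy(mirna_seq: str, window_seq: str) -> float:
    """Minimal intermolecular duplex energy (kcal/mol) between a miRNA and
    a UTR window; exhaustive over pairings via DP.  Stacked pairs score the
    shared nearest-neighbor table; unpaired nucleotides between paired
    neighbors cost a per-nt bulge penalty."""
    m = to_dna(mirna_seq)
    u = to_dna(window_seq)
    n, L = len(u), len(m)
    # E[i][j]: best energy of a duplex whose last pair is (u[i], m[j]);
    # miRNA runs antiparallel, so successors increase i and decrease j.
    E = {}
    best = 0.0
    order = [(i, j) for i in range(n) for j in range(L - 1, -1, -1)]
    for i, j in order:
        key = _pair_key(u[i], m[j])
        if key is None:
            continue
        e_here = 0  # opening pair costs nothing
        for di in range(1, MAX_BULGE + 2):
            for dj in range(1, MAX_BULGE + 2):
                pi, pj = i - di, j + dj
                if pi < 0 or pj >= L:
                    continue
                prev = E.get((pi, pj))
                if prev is None:
                    continue
                gap = (di - 1) + (dj - 1)
                stack = STACK_ENERGY[key] if gap == 0 else 0
                cand = prev + stack + gap * BULGE_PENALTY
                if cand < e_here:
                    e_here = cand
        E[(i, j)] = e_here
        if e_here < best:
            best = e_here
    return best / 10.0


def duplex_scan(mirna_name: str, mirna_seq: str, utr_name: str, utr_seq: str,
                *, threshold: float = DUPLEX_THRESHOLD,
                window: int | None = None, step: int | None = None,
                ) -> list[TargetSite]:
    """Scan UTR windows; report the minimal-energy window per locus with
    duplex_energy <= threshold.  Adjacent qualifying windows are merged and
    re-evaluated so each locus yields one site."""
    mir, utr = to_dna(mirna_seq), to_dna(utr_seq)
    w = window or (len(mir) + 8)
    s = step or max(1, w // 2)
    raw = []
    for start in range(0, max(1, len(utr) - w + 1), s):
        e = duplex_energy(mir, utr[start:start + w])
        if e <= threshold:
            raw.append((start, min(start + w, len(utr)), e))
    # merge overlapping qualifying windows into loci
    sites = []
    for a, b, e in raw:
        if sites and a < sites[-1].interval[1]:
            prev = sites[-1]
            iv = (prev.interval[0], b)
            sites[-1] = TargetSite(mirna_name, utr_name, iv,
                                   duplex_energy=min(prev.duplex_energy, e),
                                   predictors_hit=frozenset({"duplex"}))
        else:
            sites.append(TargetSite(mirna_name, utr_name, (a, b),
                                    duplex_energy=e,
                                    predictors_hit=frozenset({"duplex"})))
    return sites


def consensus_intersect(seed_sites, align_sites, duplex_sites,
                        ) -> tuple[list[TargetSite], dict[str, int]]:
    """Cluster predictor calls into spots and intersect.

    Calls for the same miRNA and transcript merge into one spot when their
    intervals overlap by >= 1 nt (transitively).  A spot is consensus when
    all three predictors contribute.  Returns (consensus sites, Venn counts
    with keys seed/align/duplex, seed&align, seed&duplex, align&duplex,
    all three).
    """
    groups: dict[tuple[str, str], list[TargetSite]] = {}
    for s in list(seed_sites) + list(align_sites) + list(duplex_sites):
        groups.setdefault((s.mirna, s.transcript), []).append(s)

    venn = {"seed": 0, "align": 0, "duplex": 0,
            "seed&align": 0, "seed&duplex": 0, "align&duplex": 0,
            "seed&align&duplex": 0}
    consensus: list[TargetSite] = []
    for (mirna, tx), sites in sorted(groups.items()):
        sites.sort(key=lambda t: t.interval)
        clusters: list[list[TargetSite]] = []
        for site in sites:
            if clusters and site.interval[0] < max(
                    x.interval[1] for x in clusters[-1]):
                clusters[-1].append(site)
            else:
                clusters.append([site])
        for cl in clusters:
            preds = frozenset().union(*(x.predictors_hit for x in cl))
            for p in preds:
                venn[p] += 1
            for pair in ("seed&align", "seed&duplex", "align&duplex"):
                a, b = pair.split("&")
                if a in preds and b in preds:
                    venn[pair] += 1
            if preds == {"seed", "align", "duplex"}:
                venn["seed&align&duplex"] += 1
                iv = (min(x.interval[0] for x in cl),
                      max(x.interval[1] for x in cl))
                stype = max((x.site_type for x in cl),
                            key=lambda t: _SITE_RANK[t])
                consensus.append(TargetSite(
                    mirna, tx, iv, site_type=stype,
                    align_score=max(x.align_score for x in cl),
                    duplex_energy=min(x.duplex_energy for x in cl),
                    predictors_hit=preds, consensus=True))
    return consensus, venn


def predict_targets(mirnas: dict[str, str], utrs: dict[str, str],
                    *, align_threshold: float = ALIGN_THRESHOLD,
                    duplex_threshold: float = DUPLEX_THRESHOLD,
                    seed_min_type: str = SEED_MIN_TYPE):
    """Run all three predictors over every (miRNA, UTR) pair and intersect."""
    seed_all, align_all, duplex_all = [], [], []
    for mname, mseq in mirnas.items():
        for uname, useq in utrs.items():
            seed_all += seed_scan(mname, mseq, uname, useq,
                                  min_type=seed_min_type)
            align_all += align_scan(mname, mseq, uname, useq,
                                    threshold=align_threshold)
            duplex_all += duplex_scan(mname, mseq, uname, useq,
                                      threshold=duplex_threshold)
    return consensus_intersect(seed_all, align_all, duplex_all)
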