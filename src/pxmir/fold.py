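"""Secondary-structure folding with a simplified stacking-energy model.

This is a deliberately small energy model, not a Turner-parameter
reimplementation: the pipeline only consumes a minimum-free-energy (MFE)
number and a dot-bracket string to support hairpin-based miRNA candidate
filtering (the ``MFE < -19 kcal/mol`` criterion) and the shuffle
randomization test.

Model
-----
* Allowed pairs: Watson–Crick (A:U, G:C) plus the G:U wobble.
* A base pair stacked directly on another pair contributes one energy per
  pair type (see ``STACK_ENERGY``); other pairs contribute nothing.
* A pair whose interior is completely unpaired closes a hairpin loop and
  costs a constant penalty; the minimum hairpin loop is 3 nt.
* A pair enclosing inner structure on which it does not stack (bulges,
  internal loops, multiloops alike) costs a constant internal penalty, so
  scattered short helices do not accumulate spurious stability.
* The unfolded chain has energy 0, so the MFE is never positive.

Energies are handled internally as integers in tenths of kcal/mol so ties
are exact; ties are broken by maximizing the number of pairs, then by
pairing the 5'-most base during traceback.
"""

from __future__ import annotations

from ._seq import to_rna

__all__ = [
    "fold",
    "structure_energy",
    "pair_allowed",
    "STACK_ENERGY",
    "HAIRPIN_PENALTY",
    "INTERNAL_PENALTY",
    "MIN_LOOP",
]

#: stacking energy (tenths of kcal/mol) contributed by a pair sitting
#: directly on another pair, keyed by the outer pair's type
STACK_ENERGY = {
    "GC": -30, "CG": -30,
    "AU": -20, "UA": -20,
    "GU": -10, "UG": -10,
}

#: constant closing penalty per hairpin loop (tenths of kcal/mol)
HAIRPIN_PENALTY = 30

#: constant penalty for a pair enclosing non-stacked structure
INTERNAL_PENALTY = 20

#: minimum number of unpaired nucleotides in a hairpin loop
MIN_LOOP = 3

_PAIRS = frozenset(STACK_ENERGY)


def pair_allowed(a: str, b: str) -> bool:
    return a + b in _PAIRS


def structure_energy(sequence: str, pairs: list[tuple[int, int]]) -> int:
    """Score a nested structure under the model, in tenths of kcal/mol.

    Used both internally and as the scoring half of the brute-force oracle.
    """
    s = to_rna(sequence)
    pairset = set(pairs)
    paired_pos = {i for p in pairs for i in p}
    e = 0
    for i, j in pairs:
        if (i + 1, j - 1) in pairset:
            e += STACK_ENERGY[s[i] + s[j]]
        elif not any(i < k < j for k in paired_pos):
            e += HAIRPIN_PENALTY
        else:
            e += INTERNAL_PENALTY
    return e


def fold(sequence: str) -> tuple[str, float]:
    """Fold a sequence; returns (dot-bracket structure, MFE in kcal/mol).

    Accepts DNA or RNA input (T is read as U).  Dynamic programming over
    all nested structures; O(n^3), fine for precursor-scale inputs.
    """
    s = to_rna(sequence)
    if set(s) - set("ACGUN"):
        raise ValueError(
            f"invalid alphabet in sequence: {sorted(set(s) - set('ACGUN'))}")
    n = len(s)
    if n == 0:
        return "", 0.0

    NONE = (10**9, 10**9)  # unreachable sentinel
    EMPTY = (0, 0)

    # values are (energy_tenths, -n_pairs); lexicographic min = best
    # P[i][j]  : best structure of s[i..j] in which (i,j) is paired
    # EP[i][j] : best structure of s[i..j] containing at least one pair
    P = [[NONE] * n for _ in range(n)]
    EP = [[NONE] * n for _ in range(n)]

    def plus(a, b):
        return (a[0] + b[0], a[1] + b[1])

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pair_allowed(s[i], s[j]):
                best = (HAIRPIN_PENALTY, -1)
                if j - i - 1 > MIN_LOOP:
                    if P[i + 1][j - 1] is not NONE:
                        cand = plus(P[i + 1][j - 1],
                                    (STACK_ENERGY[s[i] + s[j]], -1))
                        if cand < best:
                            best = cand
                    if EP[i + 1][j - 1] is not NONE:
                        cand = plus(EP[i + 1][j - 1], (INTERNAL_PENALTY, -1))
                        if cand < best:
                            best = cand
                P[i][j] = best
            best = EP[i + 1][j] if i + 1 < j else NONE
            for k in range(i + MIN_LOOP + 1, j + 1):
                if P[i][k] is NONE:
                    continue
                rest = EP[k + 1][j] if k + 1 < j else NONE
                for r in (EMPTY, rest):
                    if r is NONE:
                        continue
                    cand = plus(P[i][k], r)
                    if cand < best:
                        best = cand
            EP[i][j] = best

    full = EP[0][n - 1]
    if full is NONE or full > EMPTY:
        return "." * n, 0.0

    # deterministic traceback mirroring the recurrences above
    struct = ["."] * n
    todo = [("EP", 0, n - 1)]
    while todo:
        kind, i, j = todo.pop()
        if kind == "P":
            struct[i], struct[j] = "(", ")"
            target = P[i][j]
            if j - i - 1 > MIN_LOOP:
                if (P[i + 1][j - 1] is not NONE and
                        plus(P[i + 1][j - 1], (STACK_ENERGY[s[i] + s[j]], -1)) == target):
                    todo.append(("P", i + 1, j - 1))
                    continue
                if (EP[i + 1][j - 1] is not NONE and
                        plus(EP[i + 1][j - 1], (INTERNAL_PENALTY, -1)) == target):
                    todo.append(("EP", i + 1, j - 1))
                    continue
            # hairpin loop: interior stays unpaired
        else:  # EP
            target = EP[i][j]
            found = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                if P[i][k] is NONE:
                    continue
                if plus(P[i][k], EMPTY) == target:
                    todo.append(("P", i, k))
                    found = True
                    break
                rest = EP[k + 1][j] if k + 1 < j else NONE
                if rest is not NONE and plus(P[i][k], rest) == target:
                    todo.append(("P", i, k))
                    todo.append(("EP", k + 1, j))
                    found = True
                    break
            if not found:
                todo.append(("EP", i + 1, j))

    return "".join(struct), full[0] / 10.0
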