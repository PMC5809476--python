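"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_COMP_RNA = str.maketrans("ACGUTNacgutn", "UGCAANugcaan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement in the RNA alphabet (T treated as U)."""
    return seq.translate(_COMP_RNA)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def validate_nt(seq: str, *, allow_n: bool = True) -> None:
    allowed = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    bad = set(to_dna(seq)) - allowed
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)!r}")
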