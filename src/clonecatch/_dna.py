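"""Small DNA-string helpers shared across modules.

All comparisons treat ``N`` as a wildcard-free base: an ``N`` never matches
anything, including another ``N``. This keeps anchor and barcode matching
conservative in the presence of base-calling failures.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings; N matches nothing.

    Raises ``ValueError`` on length mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming: length mismatch ({len(a)} vs {len(b)})")
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            d += 1
    return d


def is_dna(seq: str) -> bool:
    """True iff ``seq`` is a non-empty string over the strict ACGT alphabet."""
    return len(seq) > 0 and set(seq) <= DNA_ALPHABET
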