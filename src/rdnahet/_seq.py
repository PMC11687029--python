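"""Small nucleotide-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random nucleotide string with expected G+C fraction ``gc``."""
    if length < 0:
        raise ValueError("length must be non-negative")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A, C, G, T
    idx = rng.choice(4, size=length, p=p)
    return _BASE_ARR[idx].tobytes().decode()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def other_bases(base: str) -> str:
    """The three substitution alternatives for ``base``."""
    return BASES.replace(base, "")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
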