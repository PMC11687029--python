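"""Variant-allele notation and normalization.

Alleles at a 1-based reference position are written as:

* ``"A"/"C"/"G"/"T"`` — substitution to that base;
* ``"-"`` — deletion of the reference base at the position (deletions are keyed
  to their first deleted base);
* ``"+SEQ"`` — insertion of ``SEQ`` immediately *after* the position
  (left-anchored to the preceding reference base).

Indels inside homopolymer runs are ambiguous in placement, so every producer
and consumer canonicalizes through :func:`normalize_variant` before alleles are
compared across detection methods or against ground truth.
"""

from __future__ import annotations

DELETION = "-"
INSERTION_PREFIX = "+"


def is_substitution(alt: str) -> bool:
    return len(alt) == 1 and alt in "ACGT"


def is_deletion(alt: str) -> bool:
    return alt == DELETION


def is_insertion(alt: str) -> bool:
    return alt.startswith(INSERTION_PREFIX)


def is_indel(alt: str) -> bool:
    return is_deletion(alt) or is_insertion(alt)


def normalize_variant(ref: str, pos: int, alt: str) -> tuple[int, str]:
    """Left-align an allele against reference sequence ``ref`` (1-based ``pos``).

    Substitutions are returned unchanged.  A deletion is shifted to the first
    position of the homopolymer run containing the deleted base; an insertion
    is rotated leftward while the base preceding the anchor equals the last
    base of the inserted string (the standard VCF-style left alignment,
    restricted to the single-reference case).
    """
    if is_substitution(alt):
        if not 1 <= pos <= len(ref):
            raise ValueError(f"position {pos} outside reference")
        return pos, alt
    if is_deletion(alt):
        while pos > 1 and ref[pos - 2] == ref[pos - 1]:
            pos -= 1
        return pos, alt
    if is_insertion(alt):
        ins = alt[1:]
        if not ins:
            raise ValueError("empty insertion allele")
        while pos >= 1 and ref[pos - 1] == ins[-1]:
            ins = ins[-1] + ins[:-1]
            pos -= 1
        return pos, INSERTION_PREFIX + ins
    raise ValueError(f"unrecognized allele {alt!r}")
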