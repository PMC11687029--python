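"""rDNA copy-number estimation from read-mapping proportions.

A tandemly repeated rDNA array is collapsed (or absent) in a genome assembly,
so the fraction of WGS reads that map to the reference rDNA unit overshoots
the unit's share of the assembly by a factor equal to the copy number.  The
estimator is

    copies = (pct reads on rDNA x assembly size) /
             (rDNA reference length x pct reads on assembly)

where the two percentages are computed independently (a read may count toward
both targets: it maps once to a unique genomic region but many times to a
repeat).  For mapping, the unit is extended circularly by one read length so
reads spanning tandem-copy junctions still count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from ._seq import reverse_complement
from .errors import InvalidInputError, InvalidParameterError
from .sequencing import Read, ReadSet
from .simulate import RdnaUnit


@dataclass(frozen=True)
class MappingStats:
    """Read-mapping proportions feeding the copy-number estimator."""

    pct_reads_on_rdna: float
    pct_reads_on_assembly: float
    rdna_length: int
    assembly_size: int
    n_reads: int = 0

    def __post_init__(self):
        if not 0.0 < self.pct_reads_on_assembly <= 1.0:
            raise InvalidParameterError(
                "pct_reads_on_assembly must be in (0, 1]"
            )
        if not 0.0 <= self.pct_reads_on_rdna <= 1.0:
            raise InvalidParameterError("pct_reads_on_rdna must be in [0, 1]")
        if self.rdna_length <= 0 or self.assembly_size <= 0:
            raise InvalidParameterError("lengths must be > 0")


def _maps(seq: str, target: str, k: int) -> bool:
    r = edlib.align(seq, target, mode="HW", task="distance", k=k)
    if r["editDistance"] >= 0:
        return True
    r = edlib.align(reverse_complement(seq), target, mode="HW", task="distance", k=k)
    return r["editDistance"] >= 0


def mapping_stats_from_reads(
    reads: ReadSet | list[Read],
    unit: RdnaUnit | str,
    assembly: str,
    identity_floor: float = 0.9,
) -> MappingStats:
    """Count reads mapping to the rDNA unit and to the assembly.

    A read counts toward a target when its best semi-global alignment (either
    orientation) reaches identity >= ``identity_floor``; the two counts are
    independent, so a read may contribute to both.
    """
    read_list = reads.reads if isinstance(reads, ReadSet) else reads
    if not read_list:
        raise InvalidInputError("no reads")
    unit_seq = unit.sequence if isinstance(unit, RdnaUnit) else unit
    max_len = max(len(r.sequence) for r in read_list)
    circular_unit = unit_seq + unit_seq[: min(max_len, len(unit_seq))]

    on_rdna = on_assembly = 0
    for read in read_list:
        k = max(1, int(math.ceil((1.0 - identity_floor) * len(read.sequence))))
        if _maps(read.sequence, circular_unit, k):
            on_rdna += 1
        if _maps(read.sequence, assembly, k):
            on_assembly += 1
    n = len(read_list)
    if on_assembly == 0:
        raise InvalidInputError(
            "no reads map to the assembly; estimator undefined"
        )
    return MappingStats(
        pct_reads_on_rdna=on_rdna / n,
        pct_reads_on_assembly=on_assembly / n,
        rdna_length=len(unit_seq),
        assembly_size=len(assembly),
        n_reads=n,
    )


def estimate_rdna_copy_number(stats: MappingStats) -> float:
    """Copy number = (pct_rdna x assembly size) / (rDNA length x pct_assembly)."""
    denom = stats.rdna_length * stats.pct_reads_on_assembly
    if denom == 0:
        raise InvalidInputError("zero denominator in copy-number estimate")
    return stats.pct_reads_on_rdna * stats.assembly_size / denom
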