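"""Reference-anchored alignment, pileups, and hard-filtered variant calling.

The caller is a site-wise binomial model over a read pileup: for every
non-reference allele with at least ``min_alt_count`` supporting reads it
computes

* ``QUAL = -10 log10 P[X >= alt_count]`` with ``X ~ Binomial(depth,
  base_error)`` — the phred-scaled probability that sequencing error alone
  produces at least the observed support;
* ``QD = QUAL / depth`` (quality by depth);
* ``FS`` — the phred-scaled two-sided Fisher exact test p-value of the
  2x2 (ref, alt) x (+, -) strand table (strand bias).

Calls are then hard-filtered at the conventional thresholds DP < 200,
QD < 2.0, QUAL < 30.0, FS > 200.0, with the depth cutoff raised to 10% of
the mean depth of called sites when that exceeds the floor.  These are stated
analogs of the GATK annotations of the same names; exact GATK numerics are
out of scope, but the thresholds keep their published values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy import stats

from ._seq import reverse_complement
from .align import Alignment, Scoring, align_to_reference
from .alleles import DELETION, INSERTION_PREFIX, normalize_variant
from .errors import InvalidInputError, InvalidParameterError
from .sequencing import CloneSet, Read, ReadSet
from .simulate import RdnaUnit

_LN10 = math.log(10.0)
_QUAL_CAP = 50000.0  # phred cap when the binomial tail underflows to 0

METHOD_CLONING = "cloning"
METHOD_AMPLICON = "amplicon"
METHOD_WGS = "wgs"

FILTER_PASS = "pass"
FILTER_FAIL_DEPTH = "fail_depth"
FILTER_FAIL_QUAL = "fail_qual"
FILTER_FAIL_QD = "fail_qd"
FILTER_FAIL_FS = "fail_fs"


# ---------------------------------------------------------------------------
# Pileup construction
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEL_INDEX = 4
_STRAND_INDEX = {"+": 0, "-": 1}


@dataclass
class Pileup:
    """Per-position base/deletion counts by strand over a reference window.

    ``counts`` has shape (2 strands, 5 alleles A/C/G/T/deletion, L).
    ``insertions`` maps (1-based position, inserted sequence) — already
    left-normalized — to per-strand counts.  ``offset`` is the unit
    coordinate of the window's first base.
    """

    ref: str
    offset: int
    counts: np.ndarray
    insertions: dict[tuple[int, str], np.ndarray]
    n_reads: int = 0
    n_excluded: int = 0

    @property
    def length(self) -> int:
        return len(self.ref)

    def depth(self) -> np.ndarray:
        """Reads covering each position (bases + deletions, both strands)."""
        return self.counts.sum(axis=(0, 1))

    def positions(self) -> np.ndarray:
        return np.arange(self.offset, self.offset + self.length)

    def ref_support(self, pos: int) -> int:
        i = pos - self.offset
        b = _BASE_INDEX.get(self.ref[i])
        if b is None:
            return 0
        return int(self.counts[:, b, i].sum())


def _parse_cigar(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield ch, n
            n = 0


def build_pileup(
    reads: ReadSet | list[Read],
    ref: str | RdnaUnit,
    offset: int = 1,
    identity_floor: float = 0.9,
    indel_end_exclusion: int = 5,
) -> Pileup:
    """Align reads to a reference window and accumulate a strand-aware pileup.

    Each read is aligned semi-globally (read global, reference local) in both
    orientations; the better orientation is kept.  Reads whose identity
    (1 - edit distance / read length) falls below ``identity_floor`` are
    excluded and counted in ``n_excluded``.

    Indels within ``indel_end_exclusion`` bases of either end of a read are
    not recorded: a mismatch at the very edge of a read is explained equally
    well by a boundary gap under unit edit costs, so edge indels are
    systematically unreliable.
    """
    ref_seq = ref.sequence if isinstance(ref, RdnaUnit) else ref
    if isinstance(ref, RdnaUnit):
        offset = 1
    read_list = reads.reads if isinstance(reads, ReadSet) else reads
    L = len(ref_seq)
    counts = np.zeros((2, 5, L), dtype=np.int32)
    insertions: dict[tuple[int, str], np.ndarray] = {}
    n_excluded = 0

    for read in read_list:
        seq = read.sequence
        k = max(1, int(math.ceil((1.0 - identity_floor) * len(seq))))
        fwd = edlib.align(seq, ref_seq, mode="HW", task="path", k=k)
        d_fwd = fwd["editDistance"] if fwd["editDistance"] >= 0 else math.inf
        if d_fwd <= 2:  # near-perfect forward hit: skip the reverse try
            d_rev, rev = math.inf, None
        else:
            rc = reverse_complement(seq)
            rev = edlib.align(rc, ref_seq, mode="HW", task="path", k=k)
            d_rev = rev["editDistance"] if rev["editDistance"] >= 0 else math.inf
        if d_fwd == math.inf and d_rev == math.inf:
            n_excluded += 1
            continue
        if d_fwd <= d_rev:
            res, qseq, strand = fwd, seq, "+"
        else:
            res, qseq, strand = rev, reverse_complement(seq), "-"
        if 1.0 - res["editDistance"] / len(seq) < identity_floor:
            n_excluded += 1
            continue
        si = _STRAND_INDEX[strand]
        tpos = res["locations"][0][0]  # 0-based on ref window
        cigar_ops = list(_parse_cigar(res["cigar"]))
        kinds = {op for op, _ in cigar_ops}
        if "I" in kinds and "D" in kinds:
            # Unit edit costs can re-express clustered substitutions as a
            # paired deletion+insertion; the affine aligner keeps them as
            # mismatches, stabilizing allele representation across reads.
            t_end = res["locations"][0][1]
            window = ref_seq[tpos : t_end + 1]
            cigar_ops = align_to_reference(qseq, window).cigar
        qpos = 0
        qlen = len(qseq)
        for op, n in cigar_ops:
            if op in "=MX":
                for x in range(n):
                    counts[si, _BASE_INDEX.get(qseq[qpos + x], 0), tpos + x] += 1
                qpos += n
                tpos += n
            elif op == "D":  # read lacks reference bases
                if (
                    qpos >= indel_end_exclusion
                    and qlen - qpos >= indel_end_exclusion
                    and tpos >= indel_end_exclusion
                    and L - (tpos + n) >= indel_end_exclusion
                ):
                    counts[si, _DEL_INDEX, tpos : tpos + n] += 1
                tpos += n
            elif op == "I":  # read carries extra bases, anchored before tpos
                ins = qseq[qpos : qpos + n]
                if (
                    qpos >= indel_end_exclusion
                    and qlen - (qpos + n) >= indel_end_exclusion
                    and tpos >= indel_end_exclusion
                    and L - tpos >= indel_end_exclusion
                ):
                    pos1, alt = normalize_variant(
                        ref_seq, tpos, INSERTION_PREFIX + ins
                    )
                    key = (pos1 + offset - 1, alt)
                    if key not in insertions:
                        insertions[key] = np.zeros(2, dtype=np.int64)
                    insertions[key][si] += 1
                qpos += n
    return Pileup(
        ref=ref_seq,
        offset=offset,
        counts=counts,
        insertions=insertions,
        n_reads=len(read_list),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HardFilterThresholds:
    """Published hard-filter cutoffs for read-based variant calls."""

    depth_floor: float = 200.0
    mean_depth_fraction: float = 0.10
    min_qual: float = 30.0
    min_qd: float = 2.0
    max_fs: float = 200.0

    def depth_cutoff(self, mean_depth: float) -> float:
        return max(self.depth_floor, self.mean_depth_fraction * mean_depth)


@dataclass
class VariantCall:
    position: int  # 1-based on the unit
    ref_base: str
    alt_allele: str  # base, '-', or '+SEQ'
    depth: int
    alt_count: int
    frequency: float
    qual: float
    qd: float
    fs: float
    method: str
    run_id: str | None = None
    filter_status: str = FILTER_PASS

    @property
    def key(self) -> tuple[int, str]:
        return self.position, self.alt_allele


@dataclass
class VariantTable:
    calls: list[VariantCall]
    mean_depth: float
    method: str
    run_id: str | None = None

    def __len__(self) -> int:
        return len(self.calls)

    def keys(self) -> set[tuple[int, str]]:
        return {c.key for c in self.calls}

    def get(self, key: tuple[int, str]) -> VariantCall | None:
        for c in self.calls:
            if c.key == key:
                return c
        return None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "position": c.position,
                    "ref": c.ref_base,
                    "alt": c.alt_allele,
                    "depth": c.depth,
                    "alt_count": c.alt_count,
                    "frequency": c.frequency,
                    "qual": c.qual,
                    "qd": c.qd,
                    "fs": c.fs,
                    "method": c.method,
                    "run_id": c.run_id,
                    "filter": c.filter_status,
                }
                for c in self.calls
            ]
        )


def _phred_binom_tail(alt_count: int, depth: int, base_error: float) -> float:
    """-10 log10 P[X >= alt_count], X ~ Binomial(depth, base_error)."""
    if alt_count <= 0:
        return 0.0
    logsf = stats.binom.logsf(alt_count - 1, depth, base_error)
    if not np.isfinite(logsf):
        return _QUAL_CAP
    return float(min(-10.0 * logsf / _LN10, _QUAL_CAP))


def _phred_strand_bias(
    ref_plus: int, ref_minus: int, alt_plus: int, alt_minus: int
) -> float:
    """Phred-scaled two-sided Fisher exact test of strand association."""
    table = [[ref_plus, ref_minus], [alt_plus, alt_minus]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    p = max(p, 1e-300)
    return float(-10.0 * math.log10(p))


def call_variants(
    pileup: Pileup,
    base_error: float = 1e-3,
    min_alt_count: int = 5,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
    method: str = METHOD_AMPLICON,
    run_id: str | None = None,
) -> VariantTable:
    """Site-wise binomial variant calling with hard filtering.

    Every (position, non-reference allele) with support >= ``min_alt_count``
    enters the table; ``filter_status`` then records the first failed hard
    filter (depth checked first, then QUAL, QD, FS).  The depth cutoff is
    ``max(depth_floor, 10% of the mean depth over called sites)``.
    """
    if not 0.0 < base_error < 1.0:
        raise InvalidParameterError("base_error must be in (0, 1)")
    depth = pileup.depth()
    # (index, alt, alt_plus, alt_minus, site depth)
    candidates: list[tuple[int, str, int, int, int]] = []
    for i in range(pileup.length):
        dp = int(depth[i])
        if dp == 0:
            continue
        ri = _BASE_INDEX.get(pileup.ref[i])
        for alt_base, bi in _BASE_INDEX.items():
            if bi == ri:
                continue
            if int(pileup.counts[:, bi, i].sum()) >= min_alt_count:
                candidates.append(
                    (i, alt_base, int(pileup.counts[0, bi, i]),
                     int(pileup.counts[1, bi, i]), dp)
                )
    # Deletions: left-normalize first so homopolymer placements pool together.
    del_counts: dict[int, np.ndarray] = {}
    for i in range(pileup.length):
        c_p = int(pileup.counts[0, _DEL_INDEX, i])
        c_m = int(pileup.counts[1, _DEL_INDEX, i])
        if c_p + c_m == 0:
            continue
        npos, _ = normalize_variant(pileup.ref, i + 1, DELETION)
        del_counts.setdefault(npos - 1, np.zeros(2, dtype=np.int64))
        del_counts[npos - 1] += (c_p, c_m)
    for i, strands in del_counts.items():
        if int(strands.sum()) >= min_alt_count and depth[i] > 0:
            candidates.append(
                (i, DELETION, int(strands[0]), int(strands[1]), int(depth[i]))
            )
    # Insertions were normalized when the pileup was built.
    for (pos1, alt), strands in pileup.insertions.items():
        if int(strands.sum()) >= min_alt_count:
            i = pos1 - pileup.offset
            if 0 <= i < pileup.length and depth[i] > 0:
                candidates.append(
                    (i, alt, int(strands[0]), int(strands[1]), int(depth[i]))
                )

    all_depths = [dp for *_, dp in candidates]
    mean_depth = float(np.mean(all_depths)) if all_depths else float(depth.mean())
    dp_cutoff = thresholds.depth_cutoff(mean_depth)

    calls: list[VariantCall] = []
    for i, alt, alt_p, alt_m, dp in candidates:
        ref_bi = _BASE_INDEX.get(pileup.ref[i])
        ref_p = int(pileup.counts[0, ref_bi, i]) if ref_bi is not None else 0
        ref_m = int(pileup.counts[1, ref_bi, i]) if ref_bi is not None else 0
        calls.append(
            _make_call(pileup, i, alt, alt_p, alt_m, ref_p, ref_m, dp,
                       base_error, dp_cutoff, thresholds, method, run_id)
        )
    calls.sort(key=lambda c: (c.position, c.alt_allele))
    return VariantTable(calls=calls, mean_depth=mean_depth, method=method, run_id=run_id)


def _make_call(
    pileup, i, alt, alt_p, alt_m, ref_p, ref_m, dp,
    base_error, dp_cutoff, thresholds, method, run_id,
) -> VariantCall:
    alt_count = alt_p + alt_m
    qual = _phred_binom_tail(alt_count, dp, base_error)
    qd = qual / dp if dp else 0.0
    fs = _phred_strand_bias(ref_p, ref_m, alt_p, alt_m)
    if dp < dp_cutoff:
        status = FILTER_FAIL_DEPTH
    elif qual < thresholds.min_qual:
        status = FILTER_FAIL_QUAL
    elif qd < thresholds.min_qd:
        status = FILTER_FAIL_QD
    elif fs > thresholds.max_fs:
        status = FILTER_FAIL_FS
    else:
        status = FILTER_PASS
    pos1 = i + pileup.offset
    ref_base = pileup.ref[i]
    return VariantCall(
        position=pos1,
        ref_base=ref_base,
        alt_allele=alt,
        depth=dp,
        alt_count=alt_count,
        frequency=alt_count / dp,
        qual=qual,
        qd=qd,
        fs=fs,
        method=method,
        run_id=run_id,
        filter_status=status,
    )


# ---------------------------------------------------------------------------
# Clone variant detection
# ---------------------------------------------------------------------------

@dataclass
class CloneAlignment:
    """Reference-anchored clone alignment: one column per unit position.

    ``cells[c][i]`` is clone ``c``'s state at unit position ``offset + i``:
    a base, '' for a deleted position, or base+insert for an insertion
    attached after the position.  ``masked`` holds unit positions excluded
    from distance computations after artefact correction.
    """

    clone_ids: list[str]
    ref: str
    offset: int
    cells: list[list[str]]
    masked: set[int] = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.ref)

    def column_chars(self) -> list[str]:
        """Per-clone strings over unmasked columns, deletion rendered as '-'.

        Insertions relative to the reference are not represented as columns
        (they are recorded as alleles in the variant table instead)."""
        out = []
        for row in self.cells:
            chars = []
            for i, cell in enumerate(row):
                if self.offset + i in self.masked:
                    continue
                chars.append("-" if cell == "" else cell[0])
            out.append("".join(chars))
        return out

    def variable_positions(self) -> list[int]:
        """Unit positions (unmasked) where at least one clone differs."""
        res = []
        for i in range(self.length):
            pos = self.offset + i
            if pos in self.masked:
                continue
            states = {c[i] for c in self.cells}
            if len(states) > 1 or states != {self.ref[i]}:
                res.append(pos)
        return res

    def with_masked(self, positions: set[int]) -> "CloneAlignment":
        return CloneAlignment(
            clone_ids=list(self.clone_ids),
            ref=self.ref,
            offset=self.offset,
            cells=[list(r) for r in self.cells],
            masked=set(self.masked) | set(positions),
        )


def detect_clone_variants(
    clones: CloneSet,
    unit: RdnaUnit | str,
    scoring: Scoring = Scoring(),
) -> tuple[VariantTable, CloneAlignment]:
    """Align clones to the reference and emit column-wise variant calls.

    Variant frequency is clones showing the allele / total clones.  Depth is
    the clone count; QUAL/QD/FS do not apply to Sanger-sequenced clones and
    are reported as 0 with ``filter_status = pass``.
    """
    if len(clones) < 2:
        raise InvalidInputError("need >= 2 clones")
    if isinstance(unit, RdnaUnit):
        start, end = unit.span(clones.region)
        ref_seq = unit.sequence[start - 1 : end]
        offset = start
    else:
        ref_seq = unit
        offset = clones.offset

    n = len(clones)
    cells_rows: list[list[str]] = []
    allele_support: dict[tuple[int, str], int] = {}
    for clone in clones.clones:
        aln = align_to_reference(clone.sequence, ref_seq, scoring, clone.clone_id)
        row = [""] * len(ref_seq)
        qi = ri = 0
        seen: set[tuple[int, str]] = set()
        for op, ln in aln.cigar:
            if op in "=X":
                for x in range(ln):
                    row[ri + x] = clone.sequence[qi + x]
                    if op == "X":
                        npos, nalt = normalize_variant(
                            ref_seq, ri + x + 1, clone.sequence[qi + x]
                        )
                        seen.add((npos + offset - 1, nalt))
                qi += ln
                ri += ln
            elif op == "D":
                for x in range(ln):
                    npos, nalt = normalize_variant(ref_seq, ri + x + 1, DELETION)
                    seen.add((npos + offset - 1, nalt))
                ri += ln
            elif op == "I":
                ins = clone.sequence[qi : qi + ln]
                npos, nalt = normalize_variant(ref_seq, ri, INSERTION_PREFIX + ins)
                seen.add((npos + offset - 1, nalt))
                if ri > 0:
                    row[ri - 1] = row[ri - 1] + ins
                qi += ln
        cells_rows.append(row)
        for key in seen:
            allele_support[key] = allele_support.get(key, 0) + 1

    calls = []
    for (pos, alt), support in sorted(allele_support.items()):
        i = pos - offset
        ref_base = ref_seq[i] if 0 <= i < len(ref_seq) else ""
        calls.append(
            VariantCall(
                position=pos,
                ref_base=ref_base,
                alt_allele=alt,
                depth=n,
                alt_count=support,
                frequency=support / n,
                qual=0.0,
                qd=0.0,
                fs=0.0,
                method=METHOD_CLONING,
                filter_status=FILTER_PASS,
            )
        )
    table = VariantTable(
        calls=calls, mean_depth=float(n), method=METHOD_CLONING
    )
    alignment = CloneAlignment(
        clone_ids=clones.ids, ref=ref_seq, offset=offset, cells=cells_rows
    )
    return table, alignment
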