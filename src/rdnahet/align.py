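"""Global affine-gap pairwise alignment (Needleman-Wunsch / Gotoh).

This is the package's canonical aligner: ground-truth haplotype diffs,
clone-column construction, and the re-alignment of reads whose edit-distance
cigars mix gap types all pass through it, so every stage shares one variant
representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alleles import DELETION, INSERTION_PREFIX, normalize_variant
from .errors import InvalidInputError


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring.  The default gap-open penalty is set high enough
    that a run of clustered substitutions is never re-expressed as a
    net-length-zero deletion+insertion pair (2*|gap_open| > the worst
    mismatch run it could replace at desk scale), which keeps variant
    representation stable across reads and methods."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0


@dataclass
class Alignment:
    """A global pairwise alignment as a cigar over (query, reference).

    Cigar ops: '=' match, 'X' mismatch, 'I' insertion in query (consumes
    query only), 'D' deletion from query (consumes reference only).
    """

    query_id: str | None
    score: float
    cigar: list[tuple[str, int]]

    def aligned_strings(self, query: str, ref: str) -> tuple[str, str]:
        q, r, qi, ri = [], [], 0, 0
        for op, n in self.cigar:
            if op in "=X":
                q.append(query[qi : qi + n]); r.append(ref[ri : ri + n])
                qi += n; ri += n
            elif op == "I":
                q.append(query[qi : qi + n]); r.append("-" * n); qi += n
            elif op == "D":
                q.append("-" * n); r.append(ref[ri : ri + n]); ri += n
        return "".join(q), "".join(r)

    @property
    def length(self) -> int:
        return sum(n for _, n in self.cigar)


_M, _D, _I = 0, 1, 2  # traceback states: diagonal, gap-in-query, gap-in-ref


def align_to_reference(
    query: str, ref: str, scoring: Scoring = Scoring(), query_id: str | None = None
) -> Alignment:
    """Optimal global alignment of ``query`` to ``ref`` under affine gaps.

    Ties in the traceback are broken deterministically: diagonal (match or
    mismatch) over gap-in-query ('D') over gap-in-ref ('I').
    """
    if not query or not ref:
        raise InvalidInputError("sequences must be nonempty")
    n, m = len(query), len(ref)
    go, ge = scoring.gap_open, scoring.gap_extend
    NEG = -1e18

    q = np.frombuffer(query.encode(), dtype="S1")
    r = np.frombuffer(ref.encode(), dtype="S1")
    sub = np.where(q[:, None] == r[None, :], scoring.match, scoring.mismatch)

    dtype = np.float64 if n * m <= 4_000_000 else np.float32
    M = np.full((n + 1, m + 1), NEG, dtype=dtype)
    D = np.full((n + 1, m + 1), NEG, dtype=dtype)  # gap in query: consumes ref
    I = np.full((n + 1, m + 1), NEG, dtype=dtype)  # gap in ref: consumes query
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    D[0, 1:] = go + ge * (j - 1)
    i_arr = np.arange(1, n + 1)
    I[1:, 0] = go + ge * (i_arr - 1)

    jj = np.arange(m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], D[i - 1]), I[i - 1])
        M[i, 1:] = best_prev[:-1] + sub[i - 1]
        I[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], D[i - 1, 1:]) + go, I[i - 1, 1:] + ge
        )
        # D has an intra-row recurrence; solve with the running-max trick:
        # D[i,j] = max_{k<j}( max(M[i,k], I[i,k]) + go + ge*(j-k-1) )
        #        = ge*j + max_{k<j}( max(M[i,k], I[i,k]) + go - ge*(k+1) )
        t = np.maximum(M[i], I[i]) + go - ge * (jj + 1)
        run = np.maximum.accumulate(t[:-1])
        D[i, 1:] = np.maximum(D[i, 1:], run + ge * jj[1:])

    end_scores = (M[n, m], D[n, m], I[n, m])
    state = int(np.argmax(end_scores))  # argmax prefers M > D > I on ties
    score = float(end_scores[state])

    ops: list[str] = []
    i, jx = n, m
    # small tolerance for float32 accumulation on long sequences
    tol = 1e-6 if dtype == np.float64 else 1e-2
    while i > 0 or jx > 0:
        if i == 0:
            ops.extend("D" * jx)
            break
        if jx == 0:
            ops.extend("I" * i)
            break
        if state == _M:
            s = sub[i - 1, jx - 1]
            ops.append("=" if q[i - 1] == r[jx - 1] else "X")
            prev = (M[i - 1, jx - 1], D[i - 1, jx - 1], I[i - 1, jx - 1])
            state = _pick(prev, M[i, jx] - s, tol)
            i -= 1
            jx -= 1
        elif state == _D:
            ops.append("D")
            # prefer opening from M/I (tie order M > I) over extending
            prev = (M[i, jx - 1], NEG, I[i, jx - 1])
            if abs(prev[_M] - (D[i, jx] - go)) <= tol:
                state = _M
            elif abs(prev[_I] - (D[i, jx] - go)) <= tol:
                state = _I
            else:
                state = _D  # extension: D[i,jx] == D[i,jx-1] + ge
            jx -= 1
        else:  # _I
            ops.append("I")
            prev = (M[i - 1, jx], D[i - 1, jx], NEG)
            if abs(prev[_M] - (I[i, jx] - go)) <= tol:
                state = _M
            elif abs(prev[_D] - (I[i, jx] - go)) <= tol:
                state = _D
            else:
                state = _I
            i -= 1

    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return Alignment(query_id=query_id, score=score, cigar=cigar)


def _pick(prev: tuple[float, float, float], target: float, tol: float) -> int:
    for s in (_M, _D, _I):  # deterministic preference
        if abs(prev[s] - target) <= tol:
            return s
    # fall back to the closest predecessor (float32 rounding on long inputs)
    return int(np.argmin([abs(p - target) for p in prev]))




def alignment_events(
    query: str, ref: str, scoring: "Scoring | None" = None
) -> set[tuple[int, str]]:
    """Normalized variant events of ``query`` relative to ``ref``.

    Returns {(1-based ref position, allele)} with substitutions as bases,
    deletions as '-', insertions as '+SEQ', all left-normalized — the
    canonical representation shared by the truth tables and the callers.
    """
    aln = align_to_reference(query, ref, scoring or Scoring())
    events: set[tuple[int, str]] = set()
    qi = ri = 0
    for op, n in aln.cigar:
        if op == "=":
            qi += n
            ri += n
        elif op == "X":
            for x in range(n):
                events.add((ri + x + 1, query[qi + x]))
            qi += n
            ri += n
        elif op == "D":
            for x in range(n):
                events.add(normalize_variant(ref, ri + x + 1, DELETION))
            ri += n
        else:  # I
            ins = query[qi : qi + n]
            events.add(normalize_variant(ref, ri, INSERTION_PREFIX + ins))
            qi += n
    return events
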