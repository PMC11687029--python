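"""Affine-gap alignment, pileups, and the binomial hard-filtered caller."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdnahet import (
    HardFilterThresholds,
    Pileup,
    Scoring,
    align_to_reference,
    build_pileup,
    call_variants,
    detect_clone_variants,
    sample_clones,
)
from rdnahet.calling import (
    FILTER_FAIL_DEPTH,
    FILTER_PASS,
    _BASE_INDEX,
)
from rdnahet.errors import InvalidInputError
from rdnahet.sequencing import Clone, CloneSet, Read


# --- independent oracle: exhaustive affine alignment by path enumeration ----

def brute_force_affine_score(q: str, r: str, sc: Scoring) -> float:
    best = -math.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(q) and j == len(r):
            best = max(best, score)
            return
        if i < len(q) and j < len(r):
            s = sc.match if q[i] == r[j] else sc.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(q):
            g = sc.gap_extend if prev == "I" else sc.gap_open
            rec(i + 1, j, "I", score + g)
        if j < len(r):
            g = sc.gap_extend if prev == "D" else sc.gap_open
            rec(i, j + 1, "D", score + g)

    rec(0, 0, None, 0.0)
    return best


def cigar_score(cigar, q, r, sc: Scoring) -> float:
    score, qi, ri = 0.0, 0, 0
    prev = None
    for op, n in cigar:
        if op in "=X":
            for _ in range(n):
                score += sc.match if q[qi] == r[ri] else sc.mismatch
                qi += 1
                ri += 1
        elif op == "I":
            score += sc.gap_open + (n - 1) * sc.gap_extend
            qi += n
        elif op == "D":
            score += sc.gap_open + (n - 1) * sc.gap_extend
            ri += n
        prev = op
    assert qi == len(q) and ri == len(r), "cigar does not consume sequences"
    return score


class TestAlignToReference:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        q=st.text(alphabet="ACG", min_size=1, max_size=6),
        r=st.text(alphabet="ACG", min_size=1, max_size=6),
    )
    def test_matches_exhaustive_enumeration(self, q, r):
        sc = Scoring()
        aln = align_to_reference(q, r, sc)
        assert aln.score == brute_force_affine_score(q, r, sc)
        assert cigar_score(aln.cigar, q, r, sc) == aln.score

    @pytest.mark.parametrize(
        "scoring",
        [Scoring(), Scoring(match=1, mismatch=-1, gap_open=-2, gap_extend=-1),
         Scoring(match=5, mismatch=-4, gap_open=-10, gap_extend=-1)],
    )
    def test_alternative_scorings_match_oracle(self, scoring):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(30):
            q = "".join(rng.choice(bases, rng.integers(1, 7)))
            r = "".join(rng.choice(bases, rng.integers(1, 7)))
            aln = align_to_reference(q, r, scoring)
            assert aln.score == brute_force_affine_score(q, r, scoring)
            assert cigar_score(aln.cigar, q, r, scoring) == aln.score

    def test_identical_sequences(self):
        seq = "ACGTAGGCAT" * 10
        aln = align_to_reference(seq, seq)
        assert aln.cigar == [("=", 100)]
        assert aln.score == 100 * Scoring().match

    def test_single_gap_column(self):
        aln = align_to_reference("ACGT", "AGT")
        assert aln.length == 4
        assert sum(n for op, n in aln.cigar if op in "ID") == 1

    def test_single_substitution_column_at_k(self):
        ref = "ACGTACGTACGTACGTACGT"
        k = 7
        query = ref[:k] + {"A": "C", "C": "A", "G": "T", "T": "G"}[ref[k]] + ref[k + 1:]
        aln = align_to_reference(query, ref)
        ops = []
        for op, n in aln.cigar:
            ops.extend(op * n)
        assert ops.count("X") == 1 and ops[k] == "X"

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            align_to_reference("", "ACGT")


def _pileup_from_counts(ref: str, counts: np.ndarray) -> Pileup:
    return Pileup(ref=ref, offset=1, counts=counts, insertions={})


def _mono_pileup(ref: str, depth: int, alt_pos=None, alt_base=None, alt_count=0,
                 alt_plus=None):
    """Homogeneous pileup with an optional alt allele at one 0-based site."""
    L = len(ref)
    counts = np.zeros((2, 5, L), dtype=np.int32)
    for i, b in enumerate(ref):
        counts[0, _BASE_INDEX[b], i] = depth - depth // 2
        counts[1, _BASE_INDEX[b], i] = depth // 2
    if alt_pos is not None:
        ap = alt_count // 2 if alt_plus is None else alt_plus
        am = alt_count - ap
        counts[0, _BASE_INDEX[alt_base], alt_pos] += ap
        counts[1, _BASE_INDEX[alt_base], alt_pos] += am
        counts[0, _BASE_INDEX[ref[alt_pos]], alt_pos] -= ap
        counts[1, _BASE_INDEX[ref[alt_pos]], alt_pos] -= am
    return _pileup_from_counts(ref, counts)


class TestCallVariants:
    REF = "ACGTACGTACGTACGTACGTACGTACGTAC"

    def test_low_depth_site_fails_depth_filter(self):
        # the published cutoff: read depth < 200 is discarded
        p = _mono_pileup(self.REF, 150, alt_pos=10, alt_base="A", alt_count=40)
        table = call_variants(p, base_error=0.001)
        call = table.get((11, "A"))
        assert call is not None and call.filter_status == FILTER_FAIL_DEPTH

    def test_no_alt_no_call(self):
        p = _mono_pileup(self.REF, 2000)
        assert len(call_variants(p, base_error=0.001)) == 0

    def test_balanced_strands_zero_fs(self):
        p = _mono_pileup(self.REF, 1200, alt_pos=5, alt_base="T", alt_count=200)
        call = call_variants(p, base_error=0.001).get((6, "T"))
        assert call.fs == 0.0

    def test_extreme_strand_bias_fails_fs(self):
        p = _mono_pileup(
            self.REF, 2000, alt_pos=5, alt_base="T", alt_count=300, alt_plus=300
        )
        call = call_variants(p, base_error=0.001).get((6, "T"))
        assert call.fs > 200.0
        assert call.filter_status == "fail_fs"

    def test_strong_variant_passes_qual_and_qd(self):
        p = _mono_pileup(self.REF, 2000, alt_pos=8, alt_base="C", alt_count=250)
        call = call_variants(p, base_error=0.001).get((9, "C"))
        assert call.qual > 30.0
        assert call.qd >= 2.0
        assert call.filter_status == FILTER_PASS

    def test_qual_matches_exact_binomial_tail(self):
        """Oracle: exact rational binomial tail at desk-scale depth."""
        depth, alt, err = 60, 9, 0.01
        ref = "ACGT" * 8
        p = _mono_pileup(ref, depth, alt_pos=3, alt_base="G", alt_count=alt)
        call = call_variants(
            p, base_error=err, min_alt_count=5,
            thresholds=HardFilterThresholds(depth_floor=10),
        ).get((4, "G"))
        pe = Fraction(1, 100)
        tail = sum(
            math.comb(depth, k) * pe**k * (1 - pe) ** (depth - k)
            for k in range(alt, depth + 1)
        )
        assert call.qual == pytest.approx(-10 * math.log10(float(tail)), rel=1e-6)

    def test_qd_consistency(self, its_hapset):
        from rdnahet import simulate_amplicon_reads

        lo, hi = its_hapset.unit.span("ITS")
        runs = simulate_amplicon_reads(
            its_hapset, "ITS", depth=500, read_length=150, seed=3, n_runs=1
        )
        pileup = build_pileup(
            runs[0], its_hapset.unit.sequence[lo - 1 : hi], offset=lo
        )
        table = call_variants(pileup, base_error=0.001)
        assert len(table) > 0
        for call in table.calls:
            assert call.qd * call.depth == pytest.approx(call.qual, rel=1e-9)
            assert 0 <= call.frequency <= 1
            assert call.frequency == pytest.approx(call.alt_count / call.depth)

    def test_min_alt_count_gate(self):
        p = _mono_pileup(self.REF, 2000, alt_pos=4, alt_base="A", alt_count=4)
        assert call_variants(p, base_error=0.001, min_alt_count=5).get((5, "A")) is None

    def test_depth_cutoff_tracks_mean_depth(self):
        thresholds = HardFilterThresholds()
        assert thresholds.depth_cutoff(2000) == 200
        assert thresholds.depth_cutoff(4000) == 400
        assert thresholds.depth_cutoff(500) == 200  # floor holds


class TestBuildPileup:
    def test_no_reads_zero_depth(self):
        p = build_pileup([], "ACGTACGT" * 20)
        assert p.depth().sum() == 0

    def test_single_mismatch_read(self, unit):
        ref = unit.sequence[:200]
        read_seq = ref[50:150]
        read_seq = read_seq[:30] + ("A" if read_seq[30] != "A" else "C") + read_seq[31:]
        p = build_pileup(
            [Read("r1", read_seq, "+", "test", 50, "run1")], ref
        )
        nonref = 0
        for i in range(p.length):
            for b, bi in _BASE_INDEX.items():
                if b != ref[i] and p.counts[:, bi, i].sum() > 0:
                    nonref += int(p.counts[:, bi, i].sum())
        assert nonref == 1

    def test_depth_invariant(self, its_hapset):
        from rdnahet import simulate_amplicon_reads

        lo, hi = its_hapset.unit.span("ITS")
        runs = simulate_amplicon_reads(
            its_hapset, "ITS", depth=200, read_length=100, seed=5, n_runs=1
        )
        p = build_pileup(runs[0], its_hapset.unit.sequence[lo - 1 : hi], offset=lo)
        # depth at each position equals total allele observations there
        assert (p.counts.sum(axis=(0, 1)) == p.depth()).all()
        assert (p.counts >= 0).all()

    def test_low_identity_reads_excluded(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        ref = "".join(rng.choice(bases, 300))
        junk = "".join(rng.choice(bases, 100))
        p = build_pileup([Read("r1", junk, "+", "junk", 0, "run1")], ref)
        assert p.n_excluded == 1
        assert p.depth().sum() == 0


class TestDetectCloneVariants:
    def test_shared_alt_frequency(self, unit):
        lo, hi = unit.span("ITS")
        ref = unit.sequence[lo - 1 : hi]
        mutated = ("A" if ref[100] != "A" else "C") + ref[101:]
        mutated = ref[:100] + mutated
        clones = [
            Clone(f"c{i}", mutated if i < 3 else ref, "hap1") for i in range(10)
        ]
        cs = CloneSet(clones=clones, process_error_rate=0.0, region="ITS", offset=lo)
        table, _ = detect_clone_variants(cs, unit)
        assert len(table) == 1
        assert table.calls[0].frequency == pytest.approx(0.3)
        assert table.calls[0].position == lo + 100

    def test_identical_clones_empty_table(self, unit):
        lo, hi = unit.span("ITS")
        ref = unit.sequence[lo - 1 : hi]
        cs = CloneSet(
            clones=[Clone(f"c{i}", ref, "hap1") for i in range(5)],
            process_error_rate=0.0, region="ITS", offset=lo,
        )
        table, aln = detect_clone_variants(cs, unit)
        assert len(table) == 0
        assert aln.variable_positions() == []

    def test_singleton_error_yields_single_support_call(self, unit):
        lo, hi = unit.span("ITS")
        ref = unit.sequence[lo - 1 : hi]
        bad = ref[:250] + ("G" if ref[250] != "G" else "T") + ref[251:]
        clones = [Clone(f"c{i}", ref, "hap1") for i in range(11)]
        clones.append(Clone("c11", bad, "hap1"))
        cs = CloneSet(clones=clones, process_error_rate=0.0, region="ITS", offset=lo)
        table, _ = detect_clone_variants(cs, unit)
        assert len(table) == 1
        assert table.calls[0].alt_count == 1
        assert table.calls[0].depth == 12

    def test_requires_two_clones(self, unit):
        cs = CloneSet(
            clones=[Clone("c0", unit.sequence, "hap1")],
            process_error_rate=0.0, region=None, offset=1,
        )
        with pytest.raises(InvalidInputError):
            detect_clone_variants(cs, unit)

    def test_recovers_truth_on_error_free_clones(self, its_hapset):
        cs = sample_clones(its_hapset, 40, error_rate=0.0, seed=8)
        lo, hi = its_hapset.unit.span("ITS")
        table, _ = detect_clone_variants(cs, its_hapset.unit)
        truth_in_its = {
            k for k in its_hapset.truth_keys() if lo <= k[0] <= hi
        }
        sampled_haps = {c.source_haplotype_id for c in cs.clones}
        assert sampled_haps == set(its_hapset.haplotype_ids)
        assert table.keys() == truth_in_its
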