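"""Cross-method merging, conflict taxonomy, and artefact correction."""

import pytest

from rdnahet import (
    CloneAlignment,
    VariantCall,
    VariantTable,
    classify_conflicts,
    compute_run_consistency,
    correct_clone_alignment,
    merge_methods,
)
from rdnahet.calling import (
    FILTER_FAIL_DEPTH,
    FILTER_PASS,
    METHOD_AMPLICON,
    METHOD_CLONING,
    METHOD_WGS,
)
from rdnahet.errors import InvalidInputError
from rdnahet.reconcile import (
    VERDICT_AMBIGUOUS,
    VERDICT_AMPLICON_EDGE,
    VERDICT_AMPLICON_FALSE_CALL,
    VERDICT_CLONE_UNDERSAMPLING,
    VERDICT_CLONING_ARTIFACT,
    VERDICT_CONSENSUS,
    VERDICT_REFERENCE_ERROR,
    VERDICT_RUN_INCONSISTENT,
    VERDICTS,
)


def _call(pos, alt, method, run_id=None, depth=2000, alt_count=250,
          status=FILTER_PASS, ref="A"):
    return VariantCall(
        position=pos, ref_base=ref, alt_allele=alt, depth=depth,
        alt_count=alt_count, frequency=alt_count / depth, qual=1000.0,
        qd=1000.0 / depth, fs=0.0, method=method, run_id=run_id,
        filter_status=status,
    )


def _table(calls, method, run_id=None, mean_depth=2000.0):
    return VariantTable(calls=calls, mean_depth=mean_depth, method=method,
                        run_id=run_id)


def _clone_table(support_by_key: dict, n_clones=12):
    calls = [
        VariantCall(
            position=pos, ref_base="A", alt_allele=alt, depth=n_clones,
            alt_count=c, frequency=c / n_clones, qual=0.0, qd=0.0, fs=0.0,
            method=METHOD_CLONING, filter_status=FILTER_PASS,
        )
        for (pos, alt), c in support_by_key.items()
    ]
    return _table(calls, METHOD_CLONING, mean_depth=float(n_clones))


class TestRunConsistency:
    def test_mean_frequency_across_runs(self):
        t1 = _table([_call(100, "T", METHOD_AMPLICON, "run1", alt_count=240)],
                    METHOD_AMPLICON, "run1")
        t2 = _table([_call(100, "T", METHOD_AMPLICON, "run2", alt_count=280)],
                    METHOD_AMPLICON, "run2")
        rc = compute_run_consistency([t1, t2])
        ev = rc.evidence[(100, "T")]
        assert ev.mean_frequency == pytest.approx((0.12 + 0.14) / 2)
        assert ev.consistent

    def test_partial_presence_flagged_inconsistent(self):
        t1 = _table([_call(100, "T", METHOD_AMPLICON, "run1")],
                    METHOD_AMPLICON, "run1")
        t2 = _table([], METHOD_AMPLICON, "run2")
        rc = compute_run_consistency([t1, t2])
        assert not rc.evidence[(100, "T")].consistent

    def test_single_run_trivially_consistent(self):
        t1 = _table([_call(7, "G", METHOD_AMPLICON, "run1")],
                    METHOD_AMPLICON, "run1")
        rc = compute_run_consistency([t1])
        assert rc.evidence[(7, "G")].consistent
        assert rc.n_runs == 1

    def test_requires_one_run(self):
        with pytest.raises(InvalidInputError):
            compute_run_consistency([])


class TestMergeAndClassify:
    def test_read_methods_agree_clones_missing(self):
        amp = compute_run_consistency([
            _table([_call(50, "T", METHOD_AMPLICON, "run1")], METHOD_AMPLICON, "run1"),
            _table([_call(50, "T", METHOD_AMPLICON, "run2")], METHOD_AMPLICON, "run2"),
        ])
        wgs = _table([_call(50, "T", METHOD_WGS, "wgs")], METHOD_WGS, "wgs")
        records = merge_methods(cloning=_clone_table({}), amplicon=amp, wgs=wgs)
        records = classify_conflicts(records)
        (rec,) = records
        assert rec.verdict == VERDICT_CONSENSUS
        assert rec.conflict == VERDICT_CLONE_UNDERSAMPLING

    def test_singleton_clone_is_artifact(self):
        cloning = _clone_table({(30, "G"): 1})
        amp = compute_run_consistency(
            [_table([], METHOD_AMPLICON, "run1"), _table([], METHOD_AMPLICON, "run2")]
        )
        wgs = _table([], METHOD_WGS, "wgs")
        records = classify_conflicts(
            merge_methods(cloning=cloning, amplicon=amp, wgs=wgs)
        )
        (rec,) = records
        assert rec.verdict == VERDICT_CLONING_ARTIFACT
        assert not rec.is_consensus

    def test_filter_failed_call_resurrected_by_two_methods(self):
        """A depth-failed amplicon call present in clones and WGS becomes
        consensus through the >= 2-method exception."""
        amp = compute_run_consistency([
            _table(
                [_call(80, "C", METHOD_AMPLICON, "run1", depth=150,
                       alt_count=30, status=FILTER_FAIL_DEPTH)],
                METHOD_AMPLICON, "run1",
            )
        ])
        cloning = _clone_table({(80, "C"): 3})
        wgs = _table([_call(80, "C", METHOD_WGS, "wgs")], METHOD_WGS, "wgs")
        records = classify_conflicts(
            merge_methods(cloning=cloning, amplicon=amp, wgs=wgs)
        )
        (rec,) = records
        assert rec.verdict == VERDICT_CONSENSUS

    def test_no_resurrection_from_single_method(self):
        """An allele seen by one method only, failing filters, never becomes
        consensus whatever its frequency."""
        amp = compute_run_consistency([
            _table(
                [_call(80, "C", METHOD_AMPLICON, "run1", depth=150,
                       alt_count=75, status=FILTER_FAIL_DEPTH)],
                METHOD_AMPLICON, "run1",
            ),
            _table([], METHOD_AMPLICON, "run2"),
        ])
        records = classify_conflicts(
            merge_methods(cloning=_clone_table({}), amplicon=amp,
                          wgs=_table([], METHOD_WGS, "wgs"))
        )
        (rec,) = records
        assert rec.verdict != VERDICT_CONSENSUS

    def test_reference_error_overrides_consensus(self):
        """All reads carry the alternative base: inaccurate reference."""
        amp = compute_run_consistency([
            _table([_call(10, "T", METHOD_AMPLICON, "run1", alt_count=2000)],
                   METHOD_AMPLICON, "run1")
        ])
        wgs = _table([_call(10, "T", METHOD_WGS, "wgs", alt_count=2000)],
                     METHOD_WGS, "wgs")
        records = merge_methods(amplicon=amp, wgs=wgs)
        records = classify_conflicts(
            records,
            reference_check={10: {METHOD_AMPLICON: 0, METHOD_WGS: 0}},
        )
        (rec,) = records
        assert rec.verdict == VERDICT_REFERENCE_ERROR

    def test_amplicon_edge_shadow(self):
        """Cloning-only allele 15 bp from the amplicon 3' end (window 50)."""
        cloning = _clone_table({(585, "T"): 2})
        amp = compute_run_consistency(
            [_table([], METHOD_AMPLICON, "run1")]
        )
        records = classify_conflicts(
            merge_methods(cloning=cloning, amplicon=amp),
            amplicon_spans=[(1, 600)], edge_window=50,
        )
        (rec,) = records
        assert rec.verdict == VERDICT_AMPLICON_EDGE

    def test_multiclone_allele_away_from_edge_ambiguous(self):
        cloning = _clone_table({(300, "T"): 3})
        amp = compute_run_consistency([_table([], METHOD_AMPLICON, "run1")])
        records = classify_conflicts(
            merge_methods(cloning=cloning, amplicon=amp),
            amplicon_spans=[(1, 600)], edge_window=50,
        )
        assert records[0].verdict == VERDICT_AMBIGUOUS

    def test_run_inconsistent_amplicon_allele(self):
        amp = compute_run_consistency([
            _table([_call(200, "G", METHOD_AMPLICON, "run1")],
                   METHOD_AMPLICON, "run1"),
            _table([], METHOD_AMPLICON, "run2"),
        ])
        records = classify_conflicts(
            merge_methods(cloning=_clone_table({}), amplicon=amp,
                          wgs=_table([], METHOD_WGS, "wgs"))
        )
        assert records[0].verdict == VERDICT_RUN_INCONSISTENT

    def test_single_run_false_call(self):
        amp = compute_run_consistency([
            _table([_call(327, "A", METHOD_AMPLICON, "run1")],
                   METHOD_AMPLICON, "run1"),
        ])
        records = classify_conflicts(
            merge_methods(cloning=_clone_table({}), amplicon=amp,
                          wgs=_table([], METHOD_WGS, "wgs"))
        )
        assert records[0].verdict == VERDICT_AMPLICON_FALSE_CALL

    def test_every_record_gets_exactly_one_verdict(self):
        amp = compute_run_consistency([
            _table([_call(50, "T", METHOD_AMPLICON, "run1"),
                    _call(60, "C", METHOD_AMPLICON, "run1")],
                   METHOD_AMPLICON, "run1"),
            _table([_call(50, "T", METHOD_AMPLICON, "run2")],
                   METHOD_AMPLICON, "run2"),
        ])
        cloning = _clone_table({(30, "G"): 1, (50, "T"): 4})
        wgs = _table([_call(70, "A", METHOD_WGS, "wgs")], METHOD_WGS, "wgs")
        records = classify_conflicts(
            merge_methods(cloning=cloning, amplicon=amp, wgs=wgs)
        )
        assert len(records) == 4
        for rec in records:
            assert rec.verdict in VERDICTS
            assert rec.methods_detected <= rec.methods_available

    def test_merge_requires_some_table(self):
        with pytest.raises(InvalidInputError):
            merge_methods()

    def test_all_empty_tables_give_empty_output(self):
        amp = compute_run_consistency([_table([], METHOD_AMPLICON, "run1")])
        assert merge_methods(cloning=_clone_table({}), amplicon=amp) == []


def _toy_alignment(rows: list[str], ref: str, offset=1):
    return CloneAlignment(
        clone_ids=[f"c{i}" for i in range(len(rows))],
        ref=ref,
        offset=offset,
        cells=[list(r) for r in rows],
    )


class TestCorrectCloneAlignment:
    def test_masks_singleton_artifact_column(self):
        ref = "AAAAACAAAAA"
        rows = ["AAAAACAAAAA"] * 9 + ["AAAAATAAAAA"]
        aln = _toy_alignment(rows, ref)
        rec = classify_conflicts(
            merge_methods(
                cloning=_clone_table({(6, "T"): 1}, n_clones=10),
                wgs=VariantTable([], 200.0, METHOD_WGS, "wgs"),
            )
        )
        corrected, report = correct_clone_alignment(aln, rec)
        assert report.masked_columns == [6]
        assert report.raw_variant_sites == 1
        assert report.corrected_variant_sites == 0

    def test_no_artifacts_identity(self):
        ref = "ACGTACGT"
        aln = _toy_alignment(["ACGTACGT", "ACGAACGT"], ref)
        corrected, report = correct_clone_alignment(aln, [])
        assert report.masked_columns == []
        assert report.corrected_variant_sites == report.raw_variant_sites

    def test_true_sites_survive_artifact_masking(self):
        """5 true variant columns + 3 injected singletons -> corrected = 5."""
        import numpy as np

        rng = np.random.default_rng(0)
        L = 60
        ref = "".join(rng.choice(list("ACGT"), L))
        true_pos = [5, 15, 25, 35, 45]  # 0-based
        hap2 = list(ref)
        for p in true_pos:
            hap2[p] = "A" if ref[p] != "A" else "G"
        rows = [list(ref) for _ in range(5)] + [list(hap2) for _ in range(5)]
        art_pos = [10, 30, 50]
        for k, p in enumerate(art_pos):
            rows[k][p] = "T" if ref[p] != "T" else "C"
        aln = _toy_alignment(["".join(r) for r in rows], ref)
        support = {(p + 1, rows[k][p]): 1 for k, p in enumerate(art_pos)}
        support.update({(p + 1, hap2[p]): 5 for p in true_pos})
        cloning = _clone_table(support, n_clones=10)
        wgs = _table(
            [_call(p + 1, hap2[p], METHOD_WGS, "wgs") for p in true_pos],
            METHOD_WGS, "wgs",
        )
        records = classify_conflicts(merge_methods(cloning=cloning, wgs=wgs))
        corrected, report = correct_clone_alignment(aln, records)
        assert report.raw_variant_sites == 8
        assert report.corrected_variant_sites == 5
        assert sorted(report.masked_columns) == [p + 1 for p in art_pos]
        assert sorted(corrected.variable_positions()) == [p + 1 for p in true_pos]

    def test_masking_moves_distances_both_ways(self):
        # c0 vs c1 differ only in the masked column -> distance drops to 0;
        # c0 vs c2 differ elsewhere -> distance rises (smaller denominator)
        ref = "AACAAAAAAA"
        rows = ["AACAAAAAAA", "AATAAAAAAA", "AACAAAAAGA"]
        aln = _toy_alignment(rows, ref)
        rec = classify_conflicts(
            merge_methods(
                cloning=_clone_table({(3, "T"): 1, (9, "G"): 1}, n_clones=3),
                wgs=_table([_call(9, "G", METHOD_WGS, "wgs")], METHOD_WGS, "wgs"),
            )
        )
        corrected, report = correct_clone_alignment(aln, rec)
        assert report.masked_columns == [3]
        from rdnahet import p_distance_matrix

        d_raw = p_distance_matrix(aln)
        d_corr = p_distance_matrix(corrected)
        assert d_corr.values[0, 1] < d_raw.values[0, 1]
        assert d_corr.values[0, 2] > d_raw.values[0, 2]
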