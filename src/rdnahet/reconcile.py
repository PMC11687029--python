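"""Cross-method variant reconciliation, conflict taxonomy, and correction.

Evidence from the three detection arms is merged per (position, normalized
allele).  The validity rules are:

* an allele detected by **at least two methods** is a consensus variant even
  if it failed hard filters in one of them (the resurrection exception);
  "detected" is deliberately pre-filter — cloning means >= 1 clone, amplicon
  means called in >= 1 run at any filter status, WGS means called at any
  filter status;
* an allele seen in **exactly one clone** and in no read-based method is a
  cloning artefact and is excluded from the valid list;
* a site whose reference base has **zero read support in every covering
  read-based method** indicates an inaccurate reference sequence, not a
  genuine polymorphism.

Records that are not consensus variants are classified into a conflict
taxonomy (amplicon 3'-end shadow, inadequate clone sampling, run
inconsistency, false amplicon calls, ambiguous, other) with a fixed,
configurable precedence, and artefact-only alignment columns are masked
before distances are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import (
    FILTER_PASS,
    METHOD_AMPLICON,
    METHOD_CLONING,
    METHOD_WGS,
    CloneAlignment,
    VariantTable,
)
from .errors import InvalidInputError

VERDICT_CONSENSUS = "consensus_variant"
VERDICT_CLONING_ARTIFACT = "cloning_artifact"
VERDICT_AMPLICON_EDGE = "amplicon_edge"
VERDICT_CLONE_UNDERSAMPLING = "clone_undersampling"
VERDICT_AMPLICON_FALSE_CALL = "amplicon_false_call"
VERDICT_RUN_INCONSISTENT = "run_inconsistent"
VERDICT_REFERENCE_ERROR = "reference_error"
VERDICT_AMBIGUOUS = "ambiguous"
VERDICT_OTHER = "other"

VERDICTS = (
    VERDICT_CONSENSUS,
    VERDICT_CLONING_ARTIFACT,
    VERDICT_AMPLICON_EDGE,
    VERDICT_CLONE_UNDERSAMPLING,
    VERDICT_AMPLICON_FALSE_CALL,
    VERDICT_RUN_INCONSISTENT,
    VERDICT_REFERENCE_ERROR,
    VERDICT_AMBIGUOUS,
    VERDICT_OTHER,
)

#: Report labels for the conflict-pattern tally.
CONFLICT_LABELS = {
    VERDICT_CLONING_ARTIFACT: "Artefacts caused by PCR-cloning-Sanger sequencing",
    VERDICT_AMPLICON_EDGE: "3' end of the amplicon, variant hardly detected",
    VERDICT_AMBIGUOUS: "Ambiguous to identify the source of conflict",
    VERDICT_CLONE_UNDERSAMPLING: "Inadequate clone sampling effort",
    VERDICT_AMPLICON_FALSE_CALL: "Error in high-throughput sequencing and read mapping",
    VERDICT_RUN_INCONSISTENT: "Inconsistent variant calling among independent runs",
    VERDICT_REFERENCE_ERROR: "Inaccurate reference sequence",
    VERDICT_OTHER: "Others",
}


@dataclass
class RunEvidence:
    """Per-run presence and frequency of one amplicon allele."""

    present_runs: list[str]
    n_runs: int
    freqs: dict[str, float]
    mean_frequency: float
    any_pass: bool
    filter_statuses: dict[str, str]

    @property
    def consistent(self) -> bool:
        return len(self.present_runs) == self.n_runs


@dataclass
class RunConsistency:
    """Amplicon evidence aggregated across independent runs."""

    run_ids: list[str]
    evidence: dict[tuple[int, str], RunEvidence]
    mean_depth: float = 0.0

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    def keys(self) -> set[tuple[int, str]]:
        return set(self.evidence)


def compute_run_consistency(tables: list[VariantTable]) -> RunConsistency:
    """Aggregate per-run amplicon tables into presence vectors and mean
    frequencies (averaged over the runs in which the allele was called)."""
    if not tables:
        raise InvalidInputError("need >= 1 run table")
    run_ids = [t.run_id or f"run{i + 1}" for i, t in enumerate(tables)]
    evidence: dict[tuple[int, str], RunEvidence] = {}
    keys: set[tuple[int, str]] = set()
    for t in tables:
        keys |= t.keys()
    for key in sorted(keys):
        present, freqs, statuses = [], {}, {}
        for rid, t in zip(run_ids, tables):
            call = t.get(key)
            if call is not None:
                present.append(rid)
                freqs[rid] = call.frequency
                statuses[rid] = call.filter_status
        evidence[key] = RunEvidence(
            present_runs=present,
            n_runs=len(run_ids),
            freqs=freqs,
            mean_frequency=float(np.mean(list(freqs.values()))),
            any_pass=any(s == FILTER_PASS for s in statuses.values()),
            filter_statuses=statuses,
        )
    mean_depth = float(np.mean([t.mean_depth for t in tables]))
    return RunConsistency(run_ids=run_ids, evidence=evidence, mean_depth=mean_depth)


@dataclass
class ConsensusRecord:
    """One rDNA site-allele with its cross-method evidence and verdict."""

    position: int
    ref_base: str
    alt_allele: str
    methods_available: set[str]
    methods_detected: set[str]
    clone_support: int = 0
    clone_frequency: float | None = None
    amplicon: RunEvidence | None = None
    wgs_frequency: float | None = None
    wgs_filter_status: str | None = None
    verdict: str | None = None
    conflict: str | None = None  # annotation for consensus records with a
    # method disagreement (e.g. clones missed a read-supported allele)

    @property
    def key(self) -> tuple[int, str]:
        return self.position, self.alt_allele

    @property
    def is_consensus(self) -> bool:
        return self.verdict == VERDICT_CONSENSUS


def merge_methods(
    cloning: VariantTable | None = None,
    amplicon: RunConsistency | None = None,
    wgs: VariantTable | None = None,
) -> list[ConsensusRecord]:
    """Merge per-method evidence into one record per (position, allele).

    A record becomes a preliminary consensus variant when the allele is
    detected by >= 2 methods, or when only one method has data at all and the
    allele passes that method's own criteria (cloning: >= 2 clones; amplicon:
    present in every run with a PASS call in >= 1; WGS: PASS).  Remaining
    verdicts are assigned by :func:`classify_conflicts`.
    """
    if cloning is None and amplicon is None and wgs is None:
        raise InvalidInputError("at least one method table is required")
    available: set[str] = set()
    keys: set[tuple[int, str]] = set()
    ref_bases: dict[tuple[int, str], str] = {}
    if cloning is not None:
        available.add(METHOD_CLONING)
        keys |= cloning.keys()
        for c in cloning.calls:
            ref_bases.setdefault(c.key, c.ref_base)
    if amplicon is not None:
        available.add(METHOD_AMPLICON)
        keys |= amplicon.keys()
    if wgs is not None:
        available.add(METHOD_WGS)
        keys |= wgs.keys()
        for c in wgs.calls:
            ref_bases.setdefault(c.key, c.ref_base)

    records: list[ConsensusRecord] = []
    for key in sorted(keys):
        pos, alt = key
        detected: set[str] = set()
        rec = ConsensusRecord(
            position=pos,
            ref_base=ref_bases.get(key, ""),
            alt_allele=alt,
            methods_available=set(available),
            methods_detected=detected,
        )
        if cloning is not None:
            call = cloning.get(key)
            if call is not None:
                detected.add(METHOD_CLONING)
                rec.clone_support = call.alt_count
                rec.clone_frequency = call.frequency
        if amplicon is not None and key in amplicon.evidence:
            detected.add(METHOD_AMPLICON)
            rec.amplicon = amplicon.evidence[key]
        if wgs is not None:
            call = wgs.get(key)
            if call is not None:
                detected.add(METHOD_WGS)
                rec.wgs_frequency = call.frequency
                rec.wgs_filter_status = call.filter_status

        if len(detected) >= 2:
            rec.verdict = VERDICT_CONSENSUS
        elif len(available) == 1 and detected:
            method = next(iter(detected))
            if method == METHOD_CLONING and rec.clone_support >= 2:
                rec.verdict = VERDICT_CONSENSUS
            elif (
                method == METHOD_AMPLICON
                and rec.amplicon.consistent
                and rec.amplicon.any_pass
            ):
                rec.verdict = VERDICT_CONSENSUS
            elif method == METHOD_WGS and rec.wgs_filter_status == FILTER_PASS:
                rec.verdict = VERDICT_CONSENSUS
        records.append(rec)
    return records


def classify_conflicts(
    records: list[ConsensusRecord],
    amplicon_spans: list[tuple[int, int]] | None = None,
    edge_window: int = 50,
    reference_check: dict[int, dict[str, int]] | None = None,
) -> list[ConsensusRecord]:
    """Assign one verdict per record with deterministic precedence.

    ``amplicon_spans`` lists (start, end) unit coordinates of each amplicon;
    a cloning-only allele within ``edge_window`` of the 3' end of the
    amplicon covering it is attributed to the amplicon-end coverage shadow.
    ``reference_check`` maps unit position -> {method: reference-base read
    support} for the read-based methods covering that position.

    Precedence: reference error > consensus > clone undersampling >
    cloning-only taxonomy (edge / singleton artefact / ambiguous) >
    run inconsistency > amplicon false call > other.
    """
    amplicon_spans = amplicon_spans or []
    read_methods = {METHOD_AMPLICON, METHOD_WGS}
    for rec in records:
        det_reads = rec.methods_detected & read_methods
        avail_reads = rec.methods_available & read_methods

        # 1. inaccurate reference: no read in any covering read-based method
        #    carries the reference base
        if reference_check is not None and rec.position in reference_check:
            support = reference_check[rec.position]
            if support and all(v == 0 for v in support.values()):
                rec.verdict = VERDICT_REFERENCE_ERROR
                rec.conflict = VERDICT_REFERENCE_ERROR
                continue

        # 2. consensus per merge rules (annotate residual disagreements)
        if rec.verdict == VERDICT_CONSENSUS:
            if (
                METHOD_CLONING in rec.methods_available
                and rec.clone_support == 0
                and det_reads
            ):
                rec.conflict = VERDICT_CLONE_UNDERSAMPLING
            elif rec.amplicon is not None and not rec.amplicon.consistent:
                rec.conflict = VERDICT_RUN_INCONSISTENT
            continue

        # 3. every available read method sees it, clones do not
        if (
            avail_reads
            and det_reads == avail_reads
            and METHOD_CLONING in rec.methods_available
            and rec.clone_support == 0
        ):
            rec.verdict = VERDICT_CLONE_UNDERSAMPLING
            continue

        # 4. cloning-only alleles
        if rec.methods_detected == {METHOD_CLONING}:
            near_edge = any(
                start <= rec.position <= end and end - rec.position < edge_window
                for start, end in amplicon_spans
            )
            if near_edge and METHOD_AMPLICON in rec.methods_available:
                rec.verdict = VERDICT_AMPLICON_EDGE
            elif rec.clone_support == 1:
                rec.verdict = VERDICT_CLONING_ARTIFACT
            else:
                rec.verdict = VERDICT_AMBIGUOUS
            continue

        # 5. amplicon runs disagree and WGS is absent or negative
        if (
            rec.amplicon is not None
            and rec.amplicon.present_runs
            and not rec.amplicon.consistent
            and METHOD_WGS not in rec.methods_detected
        ):
            rec.verdict = VERDICT_RUN_INCONSISTENT
            continue

        # 6. single-run amplicon allele with WGS and clones negative
        if (
            rec.methods_detected == {METHOD_AMPLICON}
            and rec.amplicon is not None
            and len(rec.amplicon.present_runs) == 1
        ):
            rec.verdict = VERDICT_AMPLICON_FALSE_CALL
            continue

        rec.verdict = VERDICT_OTHER
    return records


@dataclass
class CorrectionReport:
    """Effect of masking artefact columns on the clone alignment."""

    masked_columns: list[int]
    raw_variant_sites: int
    corrected_variant_sites: int
    raw_max_p_distance: float
    raw_mean_p_distance: float
    corrected_max_p_distance: float
    corrected_mean_p_distance: float


def correct_clone_alignment(
    alignment: CloneAlignment,
    records: list[ConsensusRecord],
    gap_mode: str = "pairwise_deletion",
) -> tuple[CloneAlignment, CorrectionReport]:
    """Mask alignment columns whose only variation is cloning artefacts.

    Returns the corrected alignment plus a report comparing raw and corrected
    variant-site counts and p-distance summaries.  Masking a column can move
    individual pairwise distances in either direction: the numerator can only
    shrink, but so does the denominator.
    """
    from .distance import distance_summary, p_distance_matrix

    by_position: dict[int, list[ConsensusRecord]] = {}
    for rec in records:
        by_position.setdefault(rec.position, []).append(rec)
    masked = {
        pos
        for pos, recs in by_position.items()
        if all(r.verdict == VERDICT_CLONING_ARTIFACT for r in recs)
        and alignment.offset <= pos < alignment.offset + alignment.length
    }

    raw_sites = len(alignment.variable_positions())
    d_raw = p_distance_matrix(
        alignment.column_chars(), labels=alignment.clone_ids, gap_mode=gap_mode
    )
    raw_max, raw_mean = distance_summary(d_raw)

    corrected = alignment.with_masked(masked)
    corr_sites = len(corrected.variable_positions())
    d_corr = p_distance_matrix(
        corrected.column_chars(), labels=corrected.clone_ids, gap_mode=gap_mode
    )
    corr_max, corr_mean = distance_summary(d_corr)

    report = CorrectionReport(
        masked_columns=sorted(masked),
        raw_variant_sites=raw_sites,
        corrected_variant_sites=corr_sites,
        raw_max_p_distance=raw_max,
        raw_mean_p_distance=raw_mean,
        corrected_max_p_distance=corr_max,
        corrected_mean_p_distance=corr_mean,
    )
    return corrected, report


def conflict_tally(records: list[ConsensusRecord]) -> dict[str, int]:
    """Count records per conflict-pattern label (consensus records contribute
    through their annotation, mirroring a post-hoc conflict table)."""
    tally = {label: 0 for label in CONFLICT_LABELS.values()}
    for rec in records:
        verdict = rec.conflict if rec.is_consensus else rec.verdict
        if verdict is None or verdict == VERDICT_CONSENSUS:
            continue
        label = CONFLICT_LABELS.get(verdict)
        if label:
            tally[label] += 1
    return tally
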