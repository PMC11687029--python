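# Methods

This note records the models, parameter choices, and numerical decisions
behind `rdnahet`, in the spirit of a simulation package's model
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The array model

A reference rDNA repeat unit is a random nucleotide string with a controlled
G+C fraction, tiled by five annotated regions in fixed order
(18S–ITS1–5.8S–ITS2–28S, 1-based inclusive coordinates). The three middle
regions are aggregated as "ITS" in all reports, matching how the barcode
region is conventionally tabulated; internally they remain separate so that
region-specific mutation rates can distinguish the 5.8S from the spacers.

Haplotypes are produced under one of three heterogeneity models:

* **Accumulated mutation** — each haplotype independently acquires
  substitutions per region (`region_rates`, substitutions/site) and indels
  (`indel_rate`; single-base by default, since the natural length spectrum
  of rDNA indel variants is poorly constrained — configurable through the
  model). Indels can be confined to one region (`indel_region`), which is
  how a study with purely ITS-localized heterogeneity is configured.
* **Hybridization** — haplotypes split into two parental clusters; the
  second cluster carries a shared substitution layer at `hybrid_divergence`
  substitutions/site, on top of which each haplotype accumulates its own
  mutations. This emulates a hybrid genome carrying two diverged repeat
  classes.
* **Foreign element** — as accumulated mutation, plus one haplotype carrying
  a random insert (`insert_length`) within the ITS.

Copy counts default to 20 total copies with every haplotype holding at least
10% of the array. This is the *detectable-variant regime*: every true allele
frequency is ≥ 0.1, large enough that a 2000× amplicon run and a 10× WGS run
both see it comfortably, and small enough that clone sampling can plausibly
miss it — the regime in which cross-method reconciliation is interesting.
Truth is recorded as the exact column-wise difference of each haplotype
against the unit, with indels left-normalized (see below) and frequencies
equal to carrying copies / total copies.

The genome model embeds all copies in tandem at the midpoint of a random
background (≥ 10× the unit length, so rDNA stays a minor genome fraction).
The assembly sequence contains *no* rDNA copy by default — tandem repeat
arrays typically collapse out of short-read assemblies entirely — which is
also the assumption under which the copy-number estimator is unbiased. A
flag instead places exactly one majority-rule consensus copy in the
assembly; with more than one physical copy this biases the estimator
downward by construction, and the option exists precisely to exercise that
behaviour.

## Sequencing-arm models and what they do not emulate

* **Cloning** (default 15 clones, error 5 × 10⁻⁴/base): each clone derives
  from one haplotype drawn ∝ copy count, with independent per-base
  substitution errors. The error rate is not directly measurable from
  published data; the default reproduces the observed order of magnitude of
  singleton artefacts per clone library (a few per ~600 bp × 12–15 clones)
  and is an exposed parameter.
* **Amplicon** (default 2000×, 150 bp single-end reads, error 10⁻³/base,
  2 runs, ±20% run-depth jitter): read starts are uniform over the
  amplicon, so coverage ramps linearly within one read length of both ends —
  the mechanism behind "variant near the amplicon 3′ end, hardly detected".
  Strand is assigned uniformly; reads are single-end because the analysis is
  site-wise and pairing adds nothing at this level.
* **WGS** (default 10×): reads uniform over the physical genome; expected
  depth on the unit ≈ coverage × copy number.

Not emulated: quality-score variation (constant-quality FASTQ), adapter
contamination, PCR duplicates, GC-coverage bias, chimera formation, and
paired-end fragment geometry. Passing tests therefore demonstrate that the
*pipeline logic* (calling, filtering, reconciliation, correction,
estimation) behaves correctly under controlled noise — not that any
particular real library preparation matches these error models.

## Alignment and variant representation

`align_to_reference` is a global affine-gap (Gotoh three-state) aligner with
deterministic traceback preference (diagonal > gap-in-query > gap-in-ref on
ties). The default scoring (match +2, mismatch −3, gap open −8, gap extend
−2) sets the gap-open penalty high enough that a cluster of nearby
substitutions is never re-expressed as a net-length-zero deletion+insertion
pair. This matters: under unit edit costs a triple substitution within a few
bases *is* cheaper as a gap pair, and a fast edit-distance mapper will
represent it that way in every read of every method, manufacturing a
cross-method-consistent phantom indel. Read mapping in `build_pileup` uses
bit-parallel banded edit distance (edlib, infix mode, both orientations) for
speed; any read whose cigar contains both an insertion and a deletion is
re-aligned with the affine aligner to restore stable representation.

Two further representation rules:

* **Left normalization.** Deletions are keyed to the first position of the
  homopolymer run containing them; insertions are rotated to their leftmost
  anchor. Generator truth, clone alignment, and read pileups all pass
  through the same normalization, so alleles match across methods by
  `(position, allele)` exactly.
* **Canonical truth.** Within one haplotype, sampled edits keep ≥ 2 bp
  spacing (a deletion adjacent to a substitution renders the same string as
  the swapped pair, so adjacent edits have no unique description), and any
  haplotype carrying an indel has its truth events re-derived by aligning
  the rendered sequence back to the unit with the canonical aligner —
  interacting edits (an insertion plus a run-boundary substitution can
  collapse into one longer insertion) are thereby recorded in the same
  representation every observer will report.
* **End exclusion.** Indels within 5 bases of a read end, or of the
  reference window edge, are not recorded: a mismatch at a read edge is
  explained equally well by a boundary gap, so edge indels are
  systematically unreliable (reads spanning tandem-copy junctions otherwise
  deposit phantom insertions at unit position 1).

The clone alignment is reference-anchored: one column per unit position,
with deletions as gap characters and insertions recorded as alleles rather
than columns. A multiple aligner would add insertion columns; at the
sub-percent divergence involved the column sets are otherwise identical.

## Caller statistics and filters

For each non-reference allele with ≥ `min_alt_count` supporting reads
(default 5 — at 2000× this keeps scattered single-read errors out of the
table while admitting every allele at frequency ≥ 0.01):

* `QUAL = −10 log₁₀ P[X ≥ alt_count]`, `X ~ Binomial(depth, base_error)`,
  capped at 5 × 10⁴ when the tail underflows;
* `QD = QUAL / depth`;
* `FS = −10 log₁₀ p` from the two-sided Fisher exact test of the
  (ref, alt) × (+, −) strand table.

These are stated analogs of the homonymous annotations produced by
haplotype-assembly callers, not reimplementations of their numerics; the
filter thresholds keep their conventional published values (DP < 200,
QUAL < 30, QD < 2, FS > 200). The depth cutoff is
`max(floor, 0.10 × mean depth of called sites)` with floor 200, encoding the
10%-of-average-depth rationale behind the published number. Multi-allelic
sites emit one record per allele. Filter failures are recorded, not
discarded: reconciliation deliberately sees pre-filter evidence because the
≥ 2-method exception rescues filter-failed calls.

## Reconciliation rules and precedence

"Detected by a method" means: ≥ 1 clone (cloning); called in ≥ 1 run at any
filter status (amplicon); called at any filter status (WGS). A record
becomes consensus when ≥ 2 methods detect it, or when only a single method
has data at all and the call passes that method's own criteria (≥ 2 clones /
present in all runs with a PASS / PASS). Conflict verdicts are assigned with
a fixed precedence chosen for determinism (the taxonomy is inherently
post-hoc): inaccurate reference (zero reference-base read support in every
covering read method) > consensus > clone undersampling > cloning-only
taxonomy (amplicon 3′-end shadow within a 50 bp window, singleton artefact,
ambiguous) > run inconsistency > single-run amplicon false call > other.
The 50 bp edge window is a package default: the coverage shadow spans about
one read length, and 50 bp is where the expected minor-allele count at
2000× falls below the caller's entry threshold.

Correction masks alignment columns whose only variation carries the
cloning-artefact verdict. Masking is *not* monotone on pairwise distances:
the mismatch count can only drop, but so does the compared-site count, so
distances between clones unaffected by the masked column rise slightly. The
tests assert both directions.

## Distances, trees, copy number

p-distances support pairwise deletion (default — the common default of
desktop phylogenetics tools, and the mode used when no deletion option is
stated) and complete deletion; both are available because the choice shifts
third-decimal values once indel artefacts are present. Neighbor joining is
the Saitou–Nei agglomeration with ties broken toward the lexicographically
smallest label pair and negative branch lengths clamped to zero with the
deficit moved to the sibling (pair totals preserved), returning an unrooted
dendropy tree. Bootstrap support and likelihood trees are out of scope: the
quantities of interest are distances and haplotype counts, not support
values.

Copy number is `(%reads on rDNA × assembly size) / (rDNA length × %reads on
assembly)`, with the two percentages computed independently over raw read
totals (a read may count toward both targets, as the formula's semantics
require). A read counts toward a target when either orientation aligns at
≥ 90% identity — the identity floor is the package's proxy for a sensitive
end-to-end mapper. The unit reference is extended circularly by one read
length so reads spanning tandem junctions map.

## Problem sizes and seeds

Desk-scale defaults were chosen once: a 1192 bp unit (592 bp ITS) for the
variant pipeline; a 1.5 kb unit with 15 kb background, 250 bp reads and 10×
coverage for copy-number studies (7/30/233 copies — the observed extremes
and a mid value of published copy-number ranges); 25 seeds for end-to-end
recovery, 20 per copy-number setting, 100 for caller calibration. Per-stage
seeds derive from one master seed through `numpy.random.SeedSequence`, so a
pipeline run is a pure function of its config; report bundles are written
without timestamps and are byte-identical across reruns.

## Known limitations

* QUAL/QD/FS are analog statistics; numeric agreement with any specific
  external caller is not expected, only threshold-level behaviour.
* The binomial caller has no local haplotype assembly, so dense variant
  clusters within one read length are called site-by-site; representation
  stability for such clusters relies on the affine re-alignment rule.
* Indels inside long homopolymers are pooled after left-normalization;
  placement within the run is not distinguishable by construction.
* The amplicon simulator draws whole-molecule templates per haplotype, so
  PCR chimeras between haplotypes (a real source of artificial recombinant
  clones) are absent.
* True indels within 5 bp of a read end or amplicon boundary are invisible
  to the read-based arms by the end-exclusion rule; clones still see them.
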