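"""Simulators for the three variant-detection arms.

Three ways of observing one rDNA array, each with its characteristic noise:

* **PCR–cloning–Sanger sequencing** — a small number of cloned molecules, each
  derived from one haplotype copy, with a per-base process error representing
  polymerase errors incorporated at any amplification/cloning stage.
* **Targeted amplicon sequencing** — deep short-read coverage of one amplified
  region, possibly over several independent runs whose mean depths differ
  (run-to-run coverage inconsistency); coverage ramps down within one read
  length of the amplicon ends, which is why variants near the 3' end of an
  amplicon are hard to detect.
* **WGS sequencing** — reads drawn uniformly from the physical genome, so the
  rDNA unit is covered at roughly (genome-wide coverage x copy number).

Every read and clone retains its source molecule, so observed allele
frequencies can be scored against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, other_bases, reverse_complement
from .errors import InvalidInputError, InvalidParameterError
from .simulate import GenomeModel, HaplotypeSet


@dataclass
class Clone:
    clone_id: str
    sequence: str
    source_haplotype_id: str


@dataclass
class CloneSet:
    """Sampled clones of one region, each derived from exactly one haplotype."""

    clones: list[Clone]
    process_error_rate: float
    region: str | None = None  # None = whole unit
    offset: int = 1  # 1-based unit coordinate of the first cloned base

    def __post_init__(self):
        if len(self.clones) < 1:
            raise InvalidInputError("CloneSet requires >= 1 clone")

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def sequences(self) -> list[str]:
        return [c.sequence for c in self.clones]

    @property
    def ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]


@dataclass
class Read:
    read_id: str
    sequence: str  # as sequenced: minus-strand reads are reverse complements
    strand: str  # '+' or '-'
    source: str  # haplotype id or 'genome'
    offset: int  # 0-based start on the source molecule (forward orientation)
    run_id: str


@dataclass
class ReadSet:
    reads: list[Read]
    read_length: int
    method: str  # 'amplicon' or 'wgs'
    run_id: str
    region: str | None = None
    offset: int = 1  # unit coordinate of the template start (amplicon only)

    def __len__(self) -> int:
        return len(self.reads)


def _apply_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> str:
    """Independent per-base substitution errors at ``error_rate``."""
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for i in rng.choice(len(seq), size=n_err, replace=False):
        out[i] = other_bases(out[i])[rng.integers(3)]
    return "".join(out)


def sample_clones(
    hapset: HaplotypeSet,
    n_clones: int,
    error_rate: float = 5e-4,
    seed: int = 0,
    region: str | None = "ITS",
) -> CloneSet:
    """Sample ``n_clones`` cloned molecules of ``region`` (default the ITS).

    Each clone's haplotype is drawn with probability proportional to its copy
    count; independent per-base substitution errors are applied at
    ``error_rate`` (default 5e-4/base, chosen to reproduce the observed order
    of magnitude of singleton cloning artefacts; exposed as a parameter).
    """
    if n_clones < 1:
        raise InvalidParameterError("n_clones must be >= 1")
    if not 0.0 <= error_rate <= 0.01:
        raise InvalidParameterError("error_rate must be in [0, 0.01]")
    if not hapset.haplotypes:
        raise InvalidInputError("empty haplotype set")
    rng = np.random.default_rng(seed)
    ids = hapset.haplotype_ids
    probs = np.array([hapset.copy_counts[h] for h in ids], dtype=float)
    probs /= probs.sum()
    start, end = hapset.unit.span(region)
    width = len(str(n_clones))
    clones = []
    for i in range(n_clones):
        hap = ids[rng.choice(len(ids), p=probs)]
        seq = _apply_errors(hapset.render(hap, start, end), error_rate, rng)
        clones.append(
            Clone(
                clone_id=f"clone{i + 1:0{width}d}",
                sequence=seq,
                source_haplotype_id=hap,
            )
        )
    return CloneSet(
        clones=clones, process_error_rate=error_rate, region=region, offset=start
    )


def simulate_amplicon_reads(
    hapset: HaplotypeSet,
    region: str | None = "ITS",
    depth: int = 2000,
    read_length: int = 150,
    error_rate: float = 1e-3,
    n_runs: int = 2,
    run_depth_jitter: float = 0.2,
    seed: int = 0,
    strand_prob: float = 0.5,
) -> list[ReadSet]:
    """Single-end amplicon reads of one region, one :class:`ReadSet` per run.

    Templates are drawn proportionally to copy counts; read starts are uniform
    over the template, so coverage ramps within ``read_length`` of the
    amplicon ends and plateaus at the target depth in the interior.  Each
    run's mean depth is ``depth x (1 + U(-jitter, +jitter))``.  Minus-strand
    reads are stored reverse-complemented, as a sequencer reports them.
    """
    if depth < 1:
        raise InvalidParameterError("depth must be >= 1")
    if n_runs < 1:
        raise InvalidParameterError("n_runs must be >= 1")
    if not 0.0 <= run_depth_jitter < 1.0:
        raise InvalidParameterError("run_depth_jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = hapset.haplotype_ids
    probs = np.array([hapset.copy_counts[h] for h in ids], dtype=float)
    probs /= probs.sum()
    start, end = hapset.unit.span(region)
    templates = {h: hapset.render(h, start, end) for h in ids}
    ref_len = end - start + 1

    runsets = []
    for run in range(1, n_runs + 1):
        run_id = f"run{run}"
        jitter = 1.0 + rng.uniform(-run_depth_jitter, run_depth_jitter)
        n_starts = max(ref_len - read_length, 0) + 1
        n_reads = max(1, round(depth * jitter * n_starts / min(read_length, ref_len)))
        reads = []
        hap_idx = rng.choice(len(ids), size=n_reads, p=probs)
        for i in range(n_reads):
            hap = ids[hap_idx[i]]
            tpl = templates[hap]
            max_start = max(len(tpl) - read_length, 0)
            off = int(rng.integers(0, max_start + 1))
            seq = _apply_errors(tpl[off : off + read_length], error_rate, rng)
            strand = "+" if rng.random() < strand_prob else "-"
            if strand == "-":
                seq = reverse_complement(seq)
            reads.append(
                Read(
                    read_id=f"{run_id}_r{i + 1}",
                    sequence=seq,
                    strand=strand,
                    source=hap,
                    offset=off,
                    run_id=run_id,
                )
            )
        runsets.append(
            ReadSet(
                reads=reads,
                read_length=read_length,
                method="amplicon",
                run_id=run_id,
                region=region,
                offset=start,
            )
        )
    return runsets


def simulate_wgs_reads(
    genome: GenomeModel,
    coverage: float = 10.0,
    read_length: int = 150,
    error_rate: float = 1e-3,
    seed: int = 0,
    strand_prob: float = 0.5,
) -> ReadSet:
    """Uniform single-end WGS reads from the physical genome.

    Expected depth over the rDNA unit is about ``coverage x total copies``
    because every tandem copy contributes reads that map back onto the single
    reference unit.
    """
    if coverage <= 0:
        raise InvalidParameterError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    g = genome.physical_genome
    n_reads = max(1, round(coverage * len(g) / read_length))
    starts = rng.integers(0, max(len(g) - read_length, 0) + 1, size=n_reads)
    reads = []
    for i, off in enumerate(starts):
        off = int(off)
        seq = _apply_errors(g[off : off + read_length], error_rate, rng)
        strand = "+" if rng.random() < strand_prob else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(
            Read(
                read_id=f"wgs_r{i + 1}",
                sequence=seq,
                strand=strand,
                source="genome",
                offset=off,
                run_id="wgs",
            )
        )
    return ReadSet(
        reads=reads, read_length=read_length, method="wgs", run_id="wgs"
    )
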