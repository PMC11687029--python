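"""Ground-truth simulation of rDNA repeat arrays.

The eukaryotic rDNA operon (18S–ITS1–5.8S–ITS2–28S) is tandemly repeated, and
under relaxed concerted evolution the copies within one genome diverge into
distinct haplotypes.  This module generates such arrays with full ground
truth: an annotated reference repeat unit, a set of haplotypes produced under
one of three heterogeneity models (independently accumulated mutations,
hybridization between two diverged parental repeat classes, or a foreign
element inserted into one copy), per-haplotype copy counts, and a background
genome in which the array is embedded.  The exact per-site allele frequencies
implied by the copy counts are recorded so that every downstream detection
step can be scored against truth.

Coordinates are 1-based and inclusive on the reference unit throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, other_bases, random_sequence
from .align import alignment_events
from .alleles import DELETION, INSERTION_PREFIX, normalize_variant
from .errors import InvalidInputError, InvalidParameterError

#: Canonical region order of the repeat unit.
REGION_NAMES = ("18S", "ITS1", "5.8S", "ITS2", "28S")
#: Sub-regions aggregated as "ITS" in reports (the fungal barcode region).
ITS_SUBREGIONS = ("ITS1", "5.8S", "ITS2")

MODES = ("accumulated_mutation", "hybridization", "foreign_element")


@dataclass(frozen=True)
class RdnaUnit:
    """Annotated reference rDNA repeat unit.

    ``regions`` is an ordered tuple of ``(name, start, end)`` with 1-based
    inclusive coordinates that tile the entire sequence in the canonical
    18S → ITS1 → 5.8S → ITS2 → 28S order.
    """

    sequence: str
    regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        names = tuple(r[0] for r in self.regions)
        if names != REGION_NAMES:
            raise InvalidParameterError(
                f"regions must be {REGION_NAMES} in order, got {names}"
            )
        cursor = 1
        for name, start, end in self.regions:
            if start != cursor:
                raise InvalidParameterError(
                    f"region {name} starts at {start}, expected {cursor}"
                )
            if end < start:
                raise InvalidParameterError(f"region {name} has length < 1")
            cursor = end + 1
        if cursor - 1 != len(self.sequence):
            raise InvalidParameterError(
                "regions do not tile the sequence: "
                f"cover {cursor - 1} of {len(self.sequence)} bases"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def span(self, region: str | None) -> tuple[int, int]:
        """(start, end) of ``region``; ``"ITS"`` = ITS1+5.8S+ITS2; None = whole unit."""
        if region is None or region == "unit":
            return 1, self.length
        if region == "ITS":
            bounds = {r[0]: (r[1], r[2]) for r in self.regions}
            return bounds["ITS1"][0], bounds["ITS2"][1]
        for name, start, end in self.regions:
            if name == region:
                return start, end
        raise InvalidParameterError(f"unknown region {region!r}")

    def region_of(self, pos: int) -> str:
        for name, start, end in self.regions:
            if start <= pos <= end:
                return name
        raise InvalidParameterError(f"position {pos} outside unit")

    def report_region_of(self, pos: int) -> str:
        """Region label used in summaries: ITS sub-regions aggregate to 'ITS'."""
        name = self.region_of(pos)
        return "ITS" if name in ITS_SUBREGIONS else name


@dataclass(frozen=True)
class HeterogeneityModel:
    """Parameters of one source of intragenomic rDNA heterogeneity.

    ``region_rates`` maps region names (``"ITS"`` is accepted as shorthand for
    all three ITS sub-regions) to per-base substitution probabilities applied
    independently per haplotype.  ``hybrid_divergence`` is the substitutions/
    site separation between the two parental repeat classes (hybridization
    mode only); ``insert_length`` the length of the foreign insert (foreign
    element mode only).
    """

    mode: str
    n_haplotypes: int
    region_rates: dict[str, float] = field(default_factory=dict)
    indel_rate: float = 0.0
    indel_region: str | None = None  # confine indels to one region (e.g. "ITS")
    hybrid_divergence: float | None = None
    insert_length: int | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise InvalidParameterError(f"mode must be one of {MODES}")
        if self.n_haplotypes < 1:
            raise InvalidParameterError("n_haplotypes must be >= 1")
        rates = list(self.region_rates.values()) + [self.indel_rate]
        if self.hybrid_divergence is not None:
            rates.append(self.hybrid_divergence)
        for r in rates:
            if not 0.0 <= r <= 0.25:
                raise InvalidParameterError(f"rate {r} outside [0, 0.25]")
        if self.mode == "hybridization":
            if self.n_haplotypes < 2:
                raise InvalidParameterError(
                    "hybridization requires n_haplotypes >= 2"
                )
            if self.hybrid_divergence is None:
                raise InvalidParameterError(
                    "hybridization requires hybrid_divergence"
                )
        if self.mode == "foreign_element" and not self.insert_length:
            raise InvalidParameterError("foreign_element requires insert_length")

    def rate_for(self, region: str) -> float:
        if region in self.region_rates:
            return self.region_rates[region]
        if region in ITS_SUBREGIONS and "ITS" in self.region_rates:
            return self.region_rates["ITS"]
        return 0.0


@dataclass(frozen=True)
class TrueVariant:
    """One ground-truth allele: 1-based unit position, ref base, alt allele,
    and the exact frequency (copies carrying the allele / total copies)."""

    position: int
    ref: str
    alt: str
    frequency: float

    @property
    def key(self) -> tuple[int, str]:
        return self.position, self.alt


@dataclass
class HaplotypeSet:
    """True haplotype sequences with copy counts and the implied truth table."""

    unit: RdnaUnit
    haplotypes: list[tuple[str, str]]
    copy_counts: dict[str, int]
    true_variant_sites: list[TrueVariant]
    _cells: dict[str, tuple[str, ...]] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        ids = [h for h, _ in self.haplotypes]
        if set(ids) != set(self.copy_counts):
            raise InvalidInputError("copy_counts keys must match haplotype ids")
        if any(c < 1 for c in self.copy_counts.values()):
            raise InvalidInputError("copy counts must be >= 1")

    @property
    def haplotype_ids(self) -> list[str]:
        return [h for h, _ in self.haplotypes]

    @property
    def total_copies(self) -> int:
        return sum(self.copy_counts.values())

    def copy_frequency(self, hap_id: str) -> float:
        return self.copy_counts[hap_id] / self.total_copies

    def render(self, hap_id: str, start: int = 1, end: int | None = None) -> str:
        """Haplotype sequence over unit coordinates ``start..end`` (1-based
        inclusive), honouring deletions/insertions within that window."""
        if end is None:
            end = self.unit.length
        cells = self._cells[hap_id]
        return "".join(cells[start - 1 : end])

    def truth_keys(self) -> set[tuple[int, str]]:
        return {v.key for v in self.true_variant_sites}


@dataclass
class GenomeModel:
    """A haplotype array embedded in a non-repetitive background genome.

    ``assembly_sequence`` emulates a genome assembly in which the tandem array
    is collapsed: it contains either no rDNA copy (the default; matches
    assemblies from which the repeats are absent entirely) or exactly one
    consensus copy.  ``physical_genome`` is what a sequencer sees: the
    background with every haplotype copy present in tandem.
    """

    background: str
    array: HaplotypeSet
    assembly_sequence: str
    total_rdna_copies: int
    physical_genome: str
    rdna_span: tuple[int, int]  # 1-based inclusive span of the array
    copy_order: list[str]

    def __post_init__(self):
        if self.total_rdna_copies != self.array.total_copies:
            raise InvalidInputError("total_rdna_copies != sum of copy counts")


def make_reference_unit(
    region_lengths: dict[str, int], gc: float = 0.5, seed: int = 0
) -> RdnaUnit:
    """Generate a random annotated reference repeat unit.

    ``region_lengths`` maps each of the five region names to its length in
    bases; all five are required and must be >= 1.  Deterministic for a fixed
    seed.
    """
    missing = [n for n in REGION_NAMES if n not in region_lengths]
    if missing:
        raise InvalidParameterError(f"missing region lengths for {missing}")
    for name in REGION_NAMES:
        if region_lengths[name] < 1:
            raise InvalidParameterError(
                f"region {name} length must be >= 1, got {region_lengths[name]}"
            )
    rng = np.random.default_rng(seed)
    total = sum(region_lengths[n] for n in REGION_NAMES)
    sequence = random_sequence(total, gc, rng)
    regions = []
    cursor = 1
    for name in REGION_NAMES:
        end = cursor + region_lengths[name] - 1
        regions.append((name, cursor, end))
        cursor = end + 1
    return RdnaUnit(sequence=sequence, regions=tuple(regions))


def _free(pos: int, occupied: set[int]) -> bool:
    """Edits within one haplotype keep >= 2 bp spacing: adjacent edits make
    the variant representation ambiguous (a deletion next to a substitution
    renders the same sequence as the substitution next to the deletion), so
    truth and any correct observer could legitimately disagree."""
    return not ({pos - 1, pos, pos + 1} & occupied)


def _sample_layer(
    unit: RdnaUnit,
    model: HeterogeneityModel,
    rng: np.random.Generator,
    taken: set[int],
) -> dict[int, str]:
    """One haplotype's private mutations: {position: allele}, avoiding
    ``taken`` (inherited edit positions) and self-adjacency."""
    edits: dict[int, str] = {}
    occupied = set(taken)
    for name, start, end in unit.regions:
        rate = model.rate_for(name)
        if rate <= 0:
            continue
        length = end - start + 1
        n = rng.binomial(length, rate)
        pool = [p for p in range(start, end + 1) if _free(p, occupied)]
        n = min(n, len(pool))
        if n == 0:
            continue
        for pos in rng.choice(pool, size=n, replace=False):
            pos = int(pos)
            if not _free(pos, occupied):
                continue
            ref = unit.sequence[pos - 1]
            edits[pos] = other_bases(ref)[rng.integers(3)]
            occupied.add(pos)
    if model.indel_rate > 0:
        lo, hi = unit.span(model.indel_region)
        lo, hi = max(lo, 2), min(hi, unit.length - 1)  # keep unit ends intact
        n = rng.binomial(hi - lo + 1, model.indel_rate)
        pool = [p for p in range(lo, hi + 1) if _free(p, occupied)]
        n = min(n, len(pool))
        if n:
            for pos in rng.choice(pool, size=n, replace=False):
                pos = int(pos)
                if not _free(pos, occupied):
                    continue
                if rng.random() < 0.5:
                    edits[pos] = DELETION
                else:
                    edits[pos] = INSERTION_PREFIX + BASES[rng.integers(4)]
                occupied.add(pos)
    return edits


def _default_copy_counts(
    ids: list[str], total_copies: int, min_copy_frac: float, rng: np.random.Generator
) -> dict[str, int]:
    base = max(1, math.ceil(min_copy_frac * total_copies))
    if base * len(ids) > total_copies:
        raise InvalidParameterError(
            f"cannot give {len(ids)} haplotypes >= {base} copies each "
            f"out of {total_copies} total"
        )
    extra = rng.multinomial(total_copies - base * len(ids), [1 / len(ids)] * len(ids))
    return {h: base + int(e) for h, e in zip(ids, extra)}


def evolve_haplotypes(
    unit: RdnaUnit,
    model: HeterogeneityModel,
    seed: int = 0,
    copy_counts: dict[str, int] | None = None,
    total_copies: int = 20,
    min_copy_frac: float = 0.1,
) -> HaplotypeSet:
    """Evolve ``model.n_haplotypes`` haplotypes from the reference unit.

    * ``accumulated_mutation`` — each haplotype independently accrues
      substitutions per region at ``region_rates`` plus indels at
      ``indel_rate``.
    * ``hybridization`` — haplotypes split into two parental clusters; the
      second cluster is separated from the first by ``hybrid_divergence``
      substitutions/site, and each haplotype additionally accrues its own
      mutations at ``region_rates``.
    * ``foreign_element`` — as accumulated mutation, but one haplotype also
      carries a random insert of ``insert_length`` bases within the ITS.

    Copy counts default to ``total_copies`` copies spread so every haplotype
    holds at least ``min_copy_frac`` of the array (the detectable-variant
    regime: every true allele frequency >= ``min_copy_frac``).

    ``true_variant_sites`` is the exact column-wise difference of each
    haplotype against the unit, with indels left-normalized and frequencies
    computed from the copy counts.
    """
    rng = np.random.default_rng(seed)
    ids = [f"hap{i + 1}" for i in range(model.n_haplotypes)]

    # Shared parental layer for hybridization mode.
    parent_b: dict[int, str] = {}
    if model.mode == "hybridization":
        n = rng.binomial(unit.length, model.hybrid_divergence)
        if n:
            for pos in rng.choice(np.arange(1, unit.length + 1), size=n, replace=False):
                pos = int(pos)
                ref = unit.sequence[pos - 1]
                parent_b[pos] = other_bases(ref)[rng.integers(3)]
    cluster_b = set(ids[len(ids) // 2 :]) if model.mode == "hybridization" else set()

    per_hap_edits: dict[str, dict[int, str]] = {}
    for hap in ids:
        inherited = dict(parent_b) if hap in cluster_b else {}
        own = _sample_layer(unit, model, rng, taken=set(inherited))
        inherited.update(own)
        per_hap_edits[hap] = inherited

    if model.mode == "foreign_element":
        its_start, its_end = unit.span("ITS")
        pos = int(rng.integers(its_start, its_end))  # insert after this base
        insert = "".join(BASES[i] for i in rng.integers(0, 4, model.insert_length))
        carrier = ids[-1]
        prev = per_hap_edits[carrier].get(pos)
        base = prev if prev and prev in BASES else None
        # attach insertion after the (possibly substituted) base at pos
        per_hap_edits[carrier][pos] = (base or "") + INSERTION_PREFIX + insert \
            if base else INSERTION_PREFIX + insert

    if copy_counts is None:
        copy_counts = _default_copy_counts(ids, total_copies, min_copy_frac, rng)
    elif set(copy_counts) != set(ids):
        raise InvalidParameterError("copy_counts keys must be the haplotype ids")
    total = sum(copy_counts.values())

    # Render per-position cells and collect normalized truth events.
    cells_by_hap: dict[str, tuple[str, ...]] = {}
    haplotypes: list[tuple[str, str]] = []
    allele_copies: dict[tuple[int, str, str], int] = {}
    for hap in ids:
        cells = list(unit.sequence)
        events: set[tuple[int, str, str]] = set()
        for pos, allele in per_hap_edits[hap].items():
            ref = unit.sequence[pos - 1]
            if allele == DELETION:
                cells[pos - 1] = ""
                npos, nalt = normalize_variant(unit.sequence, pos, DELETION)
                events.add((npos, unit.sequence[npos - 1], nalt))
            elif allele.startswith(INSERTION_PREFIX):
                cells[pos - 1] = ref + allele[1:]
                npos, nalt = normalize_variant(unit.sequence, pos, allele)
                nref = unit.sequence[npos - 1] if npos >= 1 else ""
                events.add((npos, nref, nalt))
            elif INSERTION_PREFIX in allele:  # substitution carrying an insert
                sub, ins = allele.split(INSERTION_PREFIX, 1)
                cells[pos - 1] = sub + ins
                events.add((pos, ref, sub))
                npos, nalt = normalize_variant(
                    unit.sequence, pos, INSERTION_PREFIX + ins
                )
                nref = unit.sequence[npos - 1] if npos >= 1 else ""
                events.add((npos, nref, nalt))
            else:
                cells[pos - 1] = allele
                events.add((pos, ref, allele))
        cells_by_hap[hap] = tuple(cells)
        sequence = "".join(cells)
        haplotypes.append((hap, sequence))
        if any(
            a == DELETION or INSERTION_PREFIX in a
            for a in per_hap_edits[hap].values()
        ):
            # Indels can interact with nearby edits through homopolymer runs
            # (e.g. an insertion plus a run-boundary substitution collapses
            # into a single longer insertion), so the recorded edits are not
            # necessarily the canonical diff.  Canonicalize through the same
            # affine alignment every observer uses.
            events = {
                (pos, unit.sequence[pos - 1] if pos >= 1 else "", alt)
                for pos, alt in alignment_events(sequence, unit.sequence)
            }
        for ev in events:
            allele_copies[ev] = allele_copies.get(ev, 0) + copy_counts[hap]

    truth = [
        TrueVariant(position=pos, ref=ref, alt=alt, frequency=c / total)
        for (pos, ref, alt), c in sorted(allele_copies.items())
    ]
    return HaplotypeSet(
        unit=unit,
        haplotypes=haplotypes,
        copy_counts=copy_counts,
        true_variant_sites=truth,
        _cells=cells_by_hap,
    )


def _consensus_copy(hapset: HaplotypeSet) -> str:
    """Majority-rule collapse of the array into a single unit copy."""
    out = []
    for i in range(hapset.unit.length):
        votes: dict[str, int] = {}
        for hap in hapset.haplotype_ids:
            cell = hapset._cells[hap][i]
            votes[cell] = votes.get(cell, 0) + hapset.copy_counts[hap]
        ref_cell = hapset.unit.sequence[i]
        best = max(votes, key=lambda c: (votes[c], c == ref_cell))
        out.append(best)
    return "".join(out)


def assemble_genome(
    hapset: HaplotypeSet,
    background_len: int,
    collapse_in_assembly: bool = False,
    seed: int = 0,
    gc: float = 0.5,
) -> GenomeModel:
    """Embed the haplotype array in a random non-repetitive background.

    The physical genome interleaves every haplotype copy in tandem at the
    midpoint of the background.  The assembly sequence contains the background
    only (the default, matching assemblies from which rDNA repeats are
    absent), or the background plus exactly one collapsed consensus copy.
    """
    unit_len = hapset.unit.length
    if background_len < 10 * unit_len:
        raise InvalidParameterError(
            f"background_len must be >= 10x unit length ({10 * unit_len}), "
            f"got {background_len}"
        )
    rng = np.random.default_rng(seed)
    background = random_sequence(background_len, gc, rng)

    copy_order: list[str] = []
    for hap in hapset.haplotype_ids:
        copy_order.extend([hap] * hapset.copy_counts[hap])
    rng.shuffle(copy_order)

    mid = background_len // 2
    array_seq = "".join(hapset.render(h) for h in copy_order)
    physical = background[:mid] + array_seq + background[mid:]
    rdna_span = (mid + 1, mid + len(array_seq))

    if collapse_in_assembly:
        assembly = background[:mid] + _consensus_copy(hapset) + background[mid:]
    else:
        assembly = background

    return GenomeModel(
        background=background,
        array=hapset,
        assembly_sequence=assembly,
        total_rdna_copies=hapset.total_copies,
        physical_genome=physical,
        rdna_span=rdna_span,
        copy_order=copy_order,
    )
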