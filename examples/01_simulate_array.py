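"""Simulate an rDNA repeat array with known haplotype structure.

Builds an annotated reference unit, evolves four ITS-divergent haplotypes
under the accumulated-mutation model, and embeds 20 tandem copies in a
background genome.  Prints the ground-truth variant table that every
downstream detection step is scored against.
"""

from rdnahet import (
    HeterogeneityModel,
    assemble_genome,
    evolve_haplotypes,
    make_reference_unit,
)

unit = make_reference_unit(
    {"18S": 300, "ITS1": 200, "5.8S": 160, "ITS2": 232, "28S": 300}, seed=1
)
model = HeterogeneityModel(
    mode="accumulated_mutation",
    n_haplotypes=4,
    region_rates={"ITS": 0.0065, "18S": 0.0005, "28S": 0.0005},
    indel_rate=0.0005,
)
hapset = evolve_haplotypes(unit, model, seed=2, total_copies=20)
genome = assemble_genome(hapset, background_len=12000, seed=3)

print(f"unit: {unit.length} bp, regions {[r[0] for r in unit.regions]}")
print(f"copy counts: {hapset.copy_counts} (total {hapset.total_copies})")
print(f"physical genome: {len(genome.physical_genome)} bp; "
      f"assembly (no rDNA): {len(genome.assembly_sequence)} bp")
print("\ntrue variant sites (position, ref, alt, frequency):")
for v in hapset.true_variant_sites:
    region = unit.report_region_of(max(v.position, 1))
    print(f"  {v.position:5d} {v.ref:>2} -> {v.alt:<4} {v.frequency:.2f}  [{region}]")
print("\nEach frequency is (copies carrying the allele) / (total copies); "
      "these are the values the sequencing arms should re-estimate.")
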