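"""Run the full three-arm study and reconcile variants across methods.

Executes clone sampling, two amplicon runs, and WGS on one simulated strain,
merges the evidence with the validity rules (>= 2-method consensus with the
resurrection exception; singleton-clone exclusion), and prints the conflict
taxonomy plus the per-region summary table.
"""

from rdnahet import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=11,
    region_rates={"ITS": 0.0063},
    indel_rate=2.5e-4,
    indel_region="ITS",
    n_clones=15,
    amplicon_depth=2000,
    n_runs=2,
    wgs_coverage=10.0,
)
res = run_pipeline(cfg)

print("per-region variant summary (substitutions/indels [runs or clones]):")
print(res.region_summary.to_string(index=False))

print("\nconflict tally:")
for label, count in res.conflict_summary.items():
    if count:
        print(f"  {count:3d}  {label}")

rec = res.recovery
print(f"\nconsensus variants: {rec['n_consensus']} "
      f"(recovered {rec['n_recovered']}/{rec['n_true_sites']} true sites, "
      f"{rec['n_false_consensus']} false)")
print("A perfect run recovers every true site and attributes every clone "
      "singleton to the PCR-cloning artefact class.")
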