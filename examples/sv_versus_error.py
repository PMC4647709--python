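"""Distinguish structural variation from assembly errors.

The reference is derived from the target genome by six modifications
(one duplication, one relocation, two insertions, two deletions).
Correctly assembled scaffolds then *differ* from the reference at eight
loci -- the duplication gives one difference, the relocation three (two
at its source, one at its target) -- but none of these are assembly
errors.  A purely reference-based evaluator would call all eight
errors; read evidence shows they are clean.
"""

from collections import Counter

from misasm.evidence import LibraryModel
from misasm.pipeline import run_pipeline
from misasm.simulate import (ScenarioSpec, build_scenario, naive_align_long,
                             naive_align_reads, simulate_reads, six_sv_preset)

spec = ScenarioSpec(
    genome_len=200_000,
    svs=six_sv_preset(relocation_size=15_000),
    depth=50, seed=11,
)
scenario = build_scenario(spec)
segments = naive_align_long(scenario.scaffolds, [scenario.reference])
reads = naive_align_reads(simulate_reads(scenario.genome, spec),
                          scenario.scaffolds, seed=11)
result = run_pipeline(scenario.scaffolds, segments, reads,
                      library=LibraryModel(368, 61), truth=scenario.truth)

print(f"differences between scaffolds and SV-mutated reference: "
      f"{len(result.verdicts)}")
for v in result.verdicts:
    print(f"  {v.difference.scaffold_id:<10} {v.difference.kind.value:<15}"
          f" est_size={v.difference.est_size:<6} -> {v.label.value}")
print("\nlabel counts:", dict(Counter(v.label.value for v in result.verdicts)))
sv = result.sv_evaluation
print(f"SV classification: TP={sv.tp} FP={sv.fp} FN={sv.fn} (TPR={sv.tpr:.2f})")
print("\nAll eight differences show even coverage, no disagreements and a")
print("discordant ratio below 0.1, so they are reported as correct")
print("assemblies reflecting genuine variation, not as errors --")
print("no scaffold is broken and nothing is trimmed.")
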