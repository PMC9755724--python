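"""Closing the loop: does the pipeline recover known simulation parameters?

Simulates families with configured per-region substitution rates
(MTBD 0.01, N-terminal 0.05, insert 0.30 per site per unit branch length)
and a single exonization event, runs the analysis blind, and reports how
faithfully the parameters come back: the Spearman correlation between
configured rates and measured divergence (100 - identity), and the
sensitivity/specificity/boundary error of big-exon detection.
"""

import json

from exonevo import run_recovery_experiment

result = run_recovery_experiment("exonization_recovery", n_seeds=5, base_seed=17)
first = result["replicates"][0]
print("replicate 0 region identity means:")
for name, mean in sorted(first["region_identity_means"].items()):
    print(f"  {name:6s} {mean:6.2f}%")
print("\naggregate over 5 seeds:")
print(json.dumps(result["aggregate"], indent=2))
print(
    "\nspearman_min 1.0 means rate ordering was recovered in every seed; "
    "sensitivity/specificity 1.0 with boundary error 0 means every insert "
    "was found exactly where the simulator placed it, and nowhere else."
)
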