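"""Simulate a two-condition cohort with a planted beta-band coupling.

Builds a small synthetic cohort (4 subjects × 2 conditions, 30-s
recordings) in which channels F3 and P4 share a beta oscillation whose
coupling fraction rises from 0.2 in condition A to 0.8 in condition B,
then prints basic shape and determinism facts.
"""

import numpy as np

from plinet import PlantedEdge, SyntheticConfig, generate_cohort, planted_truth

config = SyntheticConfig(
    n_subjects=4,
    duration_s=30.0,
    planted_edges=(PlantedEdge("beta", ("F3", "P4"), 0.2, 0.8),),
    seed=42,
)

cohort = generate_cohort(config)
print(f"{len(cohort)} recordings "
      f"({config.n_subjects} subjects x 2 conditions)")
rec = cohort[0].recording
print(f"each recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"at {rec.fs:g} Hz ({rec.duration_s:g} s)")
print("edges that truly differ between conditions:", planted_truth(config))

again = generate_cohort(config)
same = all(np.array_equal(a.recording.data, b.recording.data)
           for a, b in zip(cohort, again))
print(f"regenerating with the same seed is bit-identical: {same}")
# The planted edge list is the ground truth later stages should recover.
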