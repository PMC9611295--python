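"""Sliding-window PLI connectivity of a band-decomposed recording.

Generates one recording with a strongly coupled beta pair, re-references,
decomposes into the four rhythms, and computes 4-s/2-s sliding-window PLI
matrices.  The planted pair should stand far above the null level in
beta and stay at the null level in delta.
"""

import numpy as np

from plinet import (
    PlantedEdge,
    SyntheticConfig,
    WindowSpec,
    average_reference,
    connectivity_tensor,
    count_windows,
    decompose_bands,
    generate_subject,
    mean_connectivity,
)

config = SyntheticConfig(
    n_subjects=1, duration_s=60.0,
    planted_edges=(PlantedEdge("beta", ("F3", "P4"), 1.0, 1.0),),
    subject_jitter_sd=0.0, seed=7,
)
rec = average_reference(generate_subject(config, "A", 0))
spec = WindowSpec(length_s=4.0, step_s=2.0)
print(f"{count_windows(rec.n_samples, rec.fs, spec)} windows "
      f"from a {rec.duration_s:g}-s recording")

bands = decompose_bands(rec)
tensor = connectivity_tensor(bands, spec)
mean = mean_connectivity(tensor)

i, j = rec.labels.index("F3"), rec.labels.index("P4")
for band in ("delta", "theta", "alpha", "beta"):
    m = mean[band]
    null = m[np.triu_indices(60, 1)].mean()
    print(f"{band:>5}: planted pair PLI = {m[i, j]:.3f}, "
          f"grand mean over all 1770 pairs = {null:.3f}")
# A PLI near 1 marks a consistently lagged pair; the grand mean shows the
# sampling-noise floor of 4-s windows.
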