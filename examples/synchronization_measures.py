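"""Kuramoto order parameter and PLV on simulated BOLD-like signals.

Simulates phase-oscillator dynamics on a synthetic connectome, runs the
band-pass -> Hilbert -> trim phase pipeline, and prints global, gyral and
sulcal mean synchronization plus the average pairwise phase locking.
"""

import numpy as np

from foldconn import (
    GeneratorConfig,
    gen_subject,
    kop,
    phase_pipeline,
    plv,
)

config = GeneratorConfig(duration_s=240.0)
subject = gen_subject(config, group="FT", seed=5)

bundle = phase_pipeline(
    subject["series"], tr=config.tr, low=0.02, high=0.10, n_trim=50,
    rois=subject["rois"],
)
print(f"phases: {bundle.n_rois} ROIs x {bundle.n_time} samples "
      f"(50 TR trimmed per end)")
for subset in ("global", "gyri", "sulci"):
    print(f"mean {subset} synchronization: {kop(bundle, subset).mean_sync:.3f}")

p = plv(bundle)
iu = np.triu_indices(64, k=1)
print(f"mean off-diagonal PLV: {np.nanmean(p[iu]):.3f}")
print("gyral nodes carry tighter intrinsic frequencies and the densest "
      "coupling, so gyral synchronization exceeds sulcal")
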