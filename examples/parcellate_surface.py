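"""Split a cortical surface into gyral/sulcal ROIs and aggregate signals.

Builds a small synthetic surface (32 regions, 20 vertices per fold part,
curvature bimodal around +/-0.8) and runs the curvature-threshold
parcellation at r_thr = 0.15, then averages vertex time series per ROI.
"""

import numpy as np

from foldconn import (
    GeneratorConfig,
    build_roi_set,
    classify_vertices,
    gen_surface_fixture,
    roi_timeseries,
)

config = GeneratorConfig(duration_s=60.0)
surface, designed_fold, roi_series = gen_surface_fixture(config, seed=11)

fold = classify_vertices(surface.curvature, threshold=0.15)
accuracy = (fold == designed_fold).mean()
print(f"vertices: {surface.vertex_count}, fold recovery at r>0.15: "
      f"{accuracy:.1%}")

rois = build_roi_set(surface, threshold=0.15)
print(f"ROI set: {rois.n_nodes} nodes "
      f"({rois.gyral_mask.sum()} gyral, {(~rois.gyral_mask).sum()} sulcal), "
      f"{int(rois.empty_mask.sum())} empty")

ts = roi_timeseries(surface, rois)
corr = np.corrcoef(ts[0], roi_series[0])[0, 1]
print(f"node 0 series: {ts.shape[1]} samples, correlation with the "
      f"generating ROI signal r = {corr:.3f}")
print("high recovery and correlation mean the threshold parcellation "
      "reconstructs the designed fold structure and its signals")
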