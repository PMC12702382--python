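"""Functional hubs from PLV matrices and gyral/sulcal hub comparison.

Builds PLV matrices for two small synthetic groups, extracts each
subject's top-5% nodal-degree hubs, aggregates the group ranking, and
compares gyral hub counts between groups with a Mann-Whitney U test.
"""

import numpy as np

from foldconn import (
    GeneratorConfig,
    aggregate_ranking,
    gen_sc,
    hub_contingency,
    hub_profile,
    mann_whitney_u,
    phase_pipeline,
    plv,
    simulate_kuramoto,
)
from foldconn.parcellation import RoiSet

config = GeneratorConfig(duration_s=160.0)
rois = RoiSet.canonical(32)
profiles = {}
for group, base_seed in (("FT", 0), ("PT", 500)):
    group_profiles = []
    rng = np.random.default_rng(base_seed)
    adj = [gen_sc(config, group, seed=rng, rois=rois)[0].values
           for _ in range(12)]
    series = simulate_kuramoto(np.stack(adj), config, seed=rng)
    for s in range(12):
        bundle = phase_pipeline(series[s], tr=config.tr, rois=rois)
        group_profiles.append(plv(bundle))
    profiles[group] = [
        hub_profile(p, rois, fraction=0.05) for p in group_profiles
    ]

ranking = aggregate_ranking(profiles["FT"], fraction=0.10)
gyral_hubs = sum(rois.gyral_mask[i] for i in ranking.hub_set)
print(f"FT group hub set (top 10% by membership): {sorted(ranking.hub_set)} "
      f"({gyral_hubs}/{len(ranking.hub_set)} gyral)")

tables = hub_contingency(profiles["FT"], profiles["PT"], ("FT", "PT"))
print("gyral-hub contingency (subjects with 0..3 gyral hubs):")
print(f"  FT {tables['gyral'][0].tolist()}   PT {tables['gyral'][1].tolist()}")

u, p = mann_whitney_u(
    [pr.gyral_count for pr in profiles["FT"]],
    [pr.gyral_count for pr in profiles["PT"]],
    alternative="greater",
)
print(f"Mann-Whitney U (FT > PT gyral hubs): U={u:.1f}, one-sided p={p:.3f}")
print("gyral nodes dominate the hub sets; the test asks whether full-term "
      "subjects carry more gyral hubs than preterm subjects")
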