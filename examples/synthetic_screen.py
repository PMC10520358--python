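"""Simulate a paired 2D/3D screen with planted 3D-sensitive drugs and recover them.

Builds a 22-region chip (20 drugs + 2 DMSO controls), plants three drugs
with 3D-specific kill, simulates replicate spot areas with 5% lognormal
noise, and runs viability -> Z-scores -> linear distance -> hit calling.
"""

import numpy as np
import pandas as pd

from pillarscreen import (
    HitRule,
    SyntheticConfig,
    build_comparison,
    build_region_map,
    call_hits,
    generate_spot_areas,
    panel_zscores,
    relative_viability,
    aggregate_regions,
)
from pillarscreen.chip_model import ChipLayout

layout = ChipLayout(rows=4, cols=36, pitch_mm=1.5, spot_diameter_mm=0.75)
region_map = build_region_map(layout, n_regions=22, replicates_per_region=6,
                              control_region_ids=(1, 12))

# background drugs: resistant shift (3D = 2D + 55); planted: 3D-specific kill
rv2d = np.round(np.linspace(5, 95, 20))
rv3d = rv2d + 55.0
planted = [5, 11, 17]
for d in planted:
    rv2d[d - 1], rv3d[d - 1] = 50.0, 5.0
effects = pd.DataFrame({"drug_id": np.arange(1, 21),
                        "rv2d_true": rv2d, "rv3d_true": rv3d})
planted_regions = sorted(region_map.drug_region_ids[d - 1] for d in planted)
print("planted 3D-sensitive drug regions:", planted_regions)

tables = {}
for model, seed in (("2D", 101), ("3D", 102)):
    spots = generate_spot_areas(
        effects, region_map,
        SyntheticConfig(base_area_px=100.0, noise_cv=0.05, seed=seed),
        model=model,
    )
    viab = relative_viability(aggregate_regions(spots, region_map), 1, model)
    tables[model], stats = panel_zscores(viab, control_ids=(1, 12))
    print(f"{model} panel: mean {stats.mean:6.1f}%, SD {stats.sd:5.1f}% "
          f"over {stats.n_used} compounds")

comparison = call_hits(build_comparison(tables["2D"], tables["3D"]),
                       HitRule(), control_ids=(1, 12))
hits = comparison[comparison.is_hit]
print("\ncalled hits (sorted by linear distance):")
print(hits[["region_id", "z2d", "z3d", "ld"]].round(2).to_string(index=False))
print("\nrecovered planted set exactly:",
      sorted(hits.region_id) == planted_regions)
# With 5% replicate noise the three planted drugs sit ~10 noise-SDs past
# the hit thresholds, so recovery is essentially deterministic.
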