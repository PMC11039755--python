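"""Derive a physiographic resistance surface from one landscape snapshot.

Four layers — slope index, 1 − physiographic diversity (Shannon equitability
of pooled slope/flux/TPI classes), the environmental index (barriers, river
crossing costs, arid flats) and 1 − NPP — are combined by per-pixel maximum,
with low-cost overrides along coasts and river banks.
"""

import numpy as np

import paleowalk as pw

geom = pw.GridGeometry(128, 128, cell_size=2.0)
dem = pw.generate_dem(geom, seed=1)
climate = pw.generate_climate(geom, n_slices=5, seed=2)
state = pw.make_state(dem, climate.precipitation[0], float(climate.sea_level[0]), 75.0)

layers = pw.compute_morphometrics(state)
print(f"slope index: max {layers.slope_index.max():.2f} "
      f"(land mean {layers.slope_index[~state.ocean_mask].mean():.3f})")
print(f"standardised TPI: mean {layers.tpi_s_fine.mean():.1e}, sd {layers.tpi_s_fine.std():.1f} "
      "(fine scale; by construction mean 0, sd 100)")
print(f"physiographic diversity: {layers.p_div.min():.2f} to {layers.p_div.max():.2f}")

maps = pw.resistance_stack([state], climate)
cost = maps[0].cost
land = ~state.ocean_mask
print(f"resistance cost on land: median {np.median(cost[land]):.2f}, "
      f"barriers (cost = 1): {(cost >= 1.0).sum()} cells "
      f"({state.ocean_mask.sum()} ocean + {state.lake_mask.sum()} lake)")
print(f"cheap corridor/coast cells (cost <= 0.2): {(cost[land] <= 0.2).sum()} "
      "- these are the river banks and the coastal band walkers prefer")
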