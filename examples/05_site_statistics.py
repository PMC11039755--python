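"""Site visitation, occupation, migration speed and prospective ranking.

A site is accessed when a walker passes within 10 km; distinct visits are
k-means groups of the cumulative distances at access; migration speed is the
travelled distance to first access divided by the time between entry and the
site's dated age.
"""

import numpy as np

import paleowalk as pw

world = pw.two_corridor_world()
rm = pw.ResistanceMap(world.geometry, world.cost)
trajs = pw.run_ensemble([world.entry], rm, pw.MovementParams(n_steps=50_000), 30, base_seed=9)

sites = pw.generate_sites(world.land_mask, 15, (40.0, 60.0), seed=4, geometry=world.geometry)
stats = pw.compute_site_stats(trajs, sites, access_radius=10.0)

visited = [s for s in sites if stats[s.site_id].percent_visited > 0]
print(f"{len(visited)}/{len(sites)} sites visited by at least one of 30 realisations")
best = max(visited, key=lambda s: stats[s.site_id].percent_visited)
st = stats[best.site_id]
print(f"most-visited site {best.site_id}: {st.percent_visited:.0f}% of realisations, "
      f"mean {st.mean_walker_count:.0f} in-radius walker points, "
      f"mean occupation {st.occupation_numbers[st.occupation_numbers>0].mean():.1f} distinct visits")

speed = pw.migration_speed(st, entry_age=75.0, site=best)
print(f"migration speed to {best.site_id} (mean distance {st.mean_distance:.0f} km, "
      f"site age {best.age_mean:.1f} ka): {speed.speed_from_mean['age_mean']:.3f} km/yr")

# residential aggregation at the two knowledge radii
for radius in (25.0, 50.0):
    path = pw.aggregate_residential(trajs[0], radius)
    print(f"radius {radius:.0f} km: {path.n_events} mobility events, "
          f"mean {path.segment_distances.mean():.0f} km walked per event")

ranked = pw.prospect_sites(sites, stats, percent_threshold=50.0, walker_threshold=10.0, top_n=5)
print("top prospective sites:")
print(ranked.to_string(index=False))
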