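"""Tiered service-area coverage and healthcare-deficiency blind zones.

A residential area is covered at a tier when its road-network distance to
some same-tier facility (including access offsets) is within the tier
radius: 5,000 m city / 3,000 m district / 1,000 m community.  Clusters of
uncovered areas are delimited by kernel density over the uncovered points.
"""

import medaccess as m

config = m.CityConfig(
    seed=1,
    blind_zone_spec=(m.BlindZoneSpec((10_000.0, 2_000.0), 1000.0, 20, "community"),),
)
network, residential, facilities, grid, admin = m.generate_city(config)

reports = {}
for tier in ("city", "district", "community"):
    rep = m.tier_coverage(facilities, residential, network, tier, admin_units=admin)
    reports[tier] = rep
    print(f"{tier:>9}: {rep.n_covered} covered / {rep.n_uncovered} uncovered "
          f"({rep.coverage_pct:.2f}%) within {rep.radius_m:.0f} m")

rep = reports["community"]
clusters, _ = m.blind_zones(rep, residential, kde_bandwidth=800.0, grid=grid)
print(f"\ncommunity-tier blind zones ({len(clusters)} clusters above the 0.90 "
      "density quantile, ranked by uncovered households):")
planted = {a.id for a in residential if a.truth_blind}
for k, c in enumerate(clusters[:5]):
    overlap = len(planted & set(c.member_ids))
    print(f"  #{k+1}: {c.n_members} areas, {c.households:,} households"
          + (f"  <- contains {overlap}/{len(planted)} planted areas" if overlap else ""))
print(f"top-2 clusters hold {m.top_cluster_share(clusters, rep.n_uncovered):.2f}% "
      "of all uncovered areas")
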