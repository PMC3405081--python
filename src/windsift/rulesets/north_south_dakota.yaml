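# Waterfowl: predicted breeding pair density of 104 pairs/km^2 (40 pairs per
# square mile) or greater.  Whooping crane: repeated stopover sites buffered
# by 3.2 km, a site being repeated when observations span multiple years or
# three or more days in one year.  Major migratory river corridors (Missouri
# and Red Rivers) carry a 1.6 km buffer.
jurisdiction: north_south_dakota
rules:
- rule_id: nd_sd_waterfowl_pair_density
  source: waterfowl_density
  operator: density_at_least
  params:
    threshold: 104.0
- rule_id: nd_sd_tnc_priority_areas
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [tnc_priority]}
- rule_id: nd_sd_crane_stopover_sites
  source: crane_obs
  operator: repeated_stopover_buffer
  params:
    radius: 3200.0
    site_radius: 100.0
- rule_id: nd_sd_major_river_corridors
  source: rivers
  operator: line_buffer
  params:
    radius: 1600.0
    where: {field: name, in: [Missouri River, Red River]}
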