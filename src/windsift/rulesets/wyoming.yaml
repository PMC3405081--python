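jurisdiction: wyoming
rules:
- rule_id: wy_swap_priority_areas
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [swap_priority]}
- rule_id: wy_ungulate_corridors_and_ranges
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [ungulate_corridor]}
- rule_id: wy_sage_grouse_core_areas
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [sage_grouse_core]}
- rule_id: wy_priority_wetland_complexes
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [wetland_complex]}
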