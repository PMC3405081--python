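jurisdiction: alberta_saskatchewan
rules:
- rule_id: ab_sk_important_bird_areas
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [iba]}
- rule_id: ab_sk_ncc_priority_natural_areas
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [ncc_priority]}
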