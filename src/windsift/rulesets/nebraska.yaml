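# Statewide wind-wildlife sensitivity is ranked 1-6 with 6 = most sensitive;
# the four most sensitive categories are excluded, along with high-quality
# playa lakes.
jurisdiction: nebraska
rules:
- rule_id: ne_sensitivity_top_four_categories
  source: sensitivity
  operator: category_in_set
  params:
    categories: [3, 4, 5, 6]
- rule_id: ne_playa_lakes
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [playa]}
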