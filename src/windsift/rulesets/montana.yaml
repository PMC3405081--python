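# Crucial-areas layers are ranked 1-4 with 4 = highest conservation concern;
# the two highest categories are excluded.  Sage-grouse core breeding areas
# and conservancy priority areas enter as polygon burns.
jurisdiction: montana
rules:
- rule_id: mt_caps_top_two_categories
  source: caps
  operator: category_at_least
  params:
    min_category: 3
- rule_id: mt_sage_grouse_core_areas
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [sage_grouse_core]}
- rule_id: mt_tnc_priority_areas
  source: priority_polygons
  operator: polygon_burn
  params:
    where: {field: kind, in: [tnc_priority]}
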