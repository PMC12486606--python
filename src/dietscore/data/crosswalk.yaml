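# Example crosswalk: synthetic survey categories -> index components.
#
# This file documents the schema a real FoodEx2-level export crosswalk
# would use; the category ids here match the synthetic-data generator.
# Weights are the fraction of a source category's grams counted toward
# the component. For added sugar, the weight IS the added-sugar
# coefficient p_c (sugar_coefficients below repeats them for the
# standalone estimator). The sugar coefficients and the butter fat
# fraction are illustrative placeholders, not authoritative values.
#
# meat_tags drive the red-meat split: predominant species + processed
# flag per source category (a single predominant species per category,
# no proportional splitting).
version: 1
sugar_coefficients:
  sweets: 0.45
  soft_drinks: 0.09
meat_tags:
  beef: {species: beef, processed: false}
  lamb: {species: lamb, processed: false}
  pork: {species: pork, processed: false}
  sausages: {species: pork, processed: true}
  ham: {species: pork, processed: true}
crosswalks:
  WISH:
    ignore: [potatoes, alcoholic_beverages]
    entries:
      - {source: whole_grain_cereals, component: whole_grains}
      - {source: vegetables, component: vegetables}
      - {source: fruits, component: fruits}
      - {source: dairy, component: dairy}
      - {source: fish, component: fish}
      - {source: legumes, component: legumes}
      - {source: nuts, component: nuts}
      - {source: vegetable_oils, component: unsaturated_fats}
      - {source: beef, component: red_meat}
      - {source: lamb, component: red_meat}
      - {source: pork, component: red_meat}
      - {source: sausages, component: red_meat}
      - {source: ham, component: red_meat}
      - {source: poultry, component: poultry}
      - {source: eggs, component: eggs}
      - {source: butter, component: saturated_oils, weight: 0.8}
      - {source: sweets, component: added_sugar, weight: 0.45}
      - {source: soft_drinks, component: added_sugar, weight: 0.09}
  WISH2.0:
    ignore: [potatoes]
    entries:
      - {source: whole_grain_cereals, component: whole_grains}
      - {source: vegetables, component: vegetables}
      - {source: fruits, component: fruits}
      - {source: dairy, component: dairy}
      - {source: fish, component: fish}
      - {source: legumes, component: legumes}
      - {source: nuts, component: nuts}
      - {source: vegetable_oils, component: unsaturated_fats}
      - {source: beef, component: red_meat}
      - {source: lamb, component: red_meat}
      - {source: pork, component: red_meat}
      - {source: sausages, component: processed_meat}
      - {source: ham, component: processed_meat}
      - {source: poultry, component: poultry}
      - {source: eggs, component: eggs}
      - {source: butter, component: saturated_oils, weight: 0.8}
      - {source: sweets, component: added_sugar, weight: 0.45}
      - {source: soft_drinks, component: added_sugar, weight: 0.09}
      - {source: alcoholic_beverages, component: alcoholic_beverages}
  EAT-Lancet:
    ignore: [butter, alcoholic_beverages]
    entries:
      - {source: whole_grain_cereals, component: whole_grains}
      - {source: potatoes, component: potatoes}
      - {source: vegetables, component: vegetables}
      - {source: fruits, component: fruits}
      - {source: dairy, component: dairy}
      - {source: fish, component: fish}
      - {source: legumes, component: legumes}
      - {source: nuts, component: nuts}
      - {source: vegetable_oils, component: unsaturated_fats}
      - {source: beef, component: beef_lamb}
      - {source: lamb, component: beef_lamb}
      - {source: pork, component: pork}
      - {source: sausages, component: pork}
      - {source: ham, component: pork}
      - {source: poultry, component: poultry}
      - {source: eggs, component: eggs}
      - {source: sweets, component: added_sugar, weight: 0.45}
      - {source: soft_drinks, component: added_sugar, weight: 0.09}
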