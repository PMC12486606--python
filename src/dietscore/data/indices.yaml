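# Built-in index definitions (editable defaults).
#
# All intakes/thresholds are mean g/day. Values fixed by the index
# definitions themselves: whole grains 125 (100-150) g/day in WISH and
# WISH 2.0 (Global Burden of Disease recommendation); saturated-oil
# cut-off 11.8 g/day; added-sugar cut-off 31 g/day; processed meat 2-4
# g/day; alcohol zero tolerance. Every other lower/recommended/upper
# value is a package default derived from the Planetary Health Diet
# reference intakes (2500 kcal/day reference: vegetables 300 (200-600),
# fruits 200 (100-300), dairy 250 (0-500), red meat 14 (0-28), poultry
# 29 (0-58), eggs 13 (0-25), fish 28 (0-100), legumes 75 (0-100), nuts
# 50 (0-75), unsaturated oils 40 (20-80), potatoes 50 (0-100)).
#
# The EAT-Lancet ordinal band thresholds are NOT printed in the source
# index; the three thresholds per component below are package defaults
# built from the PHD target and range (quarter/half/full of the target
# for adequacy-type groups; target/midpoint/upper for moderation-type
# groups). Edit freely: the engine treats them as configuration.
version: 1
indices:
  WISH:
    per_component_max: 10
    components:
      - id: whole_grains
        display_name: Whole grains
        rule: {kind: adequacy, lower: 100.0, recommended: 125.0}
      - id: vegetables
        display_name: Vegetables
        rule: {kind: adequacy, lower: 200.0, recommended: 300.0}
      - id: fruits
        display_name: Fruits
        rule: {kind: adequacy, lower: 100.0, recommended: 200.0}
      - id: dairy
        display_name: Dairy foods
        rule: {kind: adequacy, lower: 0.0, recommended: 250.0}
      - id: fish
        display_name: Fish
        rule: {kind: adequacy, lower: 0.0, recommended: 28.0}
      - id: legumes
        display_name: Legumes
        rule: {kind: adequacy, lower: 0.0, recommended: 75.0}
      - id: nuts
        display_name: Nuts
        rule: {kind: adequacy, lower: 0.0, recommended: 50.0}
      - id: unsaturated_fats
        display_name: Unsaturated fats
        rule: {kind: adequacy, lower: 20.0, recommended: 40.0}
      - id: red_meat
        display_name: Red meat (incl. processed)
        rule: {kind: moderation, recommended: 14.0, upper: 28.0}
      - id: poultry
        display_name: Chicken and other poultry
        rule: {kind: moderation, recommended: 29.0, upper: 58.0}
      - id: eggs
        display_name: Eggs
        rule: {kind: moderation, recommended: 13.0, upper: 25.0}
      - id: saturated_oils
        display_name: Saturated oils
        rule: {kind: binary_cutoff, cutoff: 11.8}
      - id: added_sugar
        display_name: Added sugar
        rule: {kind: binary_cutoff, cutoff: 31.0}
  WISH2.0:
    per_component_max: 10
    components:
      - id: whole_grains
        display_name: Whole grains
        rule: {kind: adequacy, lower: 100.0, recommended: 125.0}
      - id: vegetables
        display_name: Vegetables
        rule: {kind: adequacy, lower: 200.0, recommended: 300.0}
      - id: fruits
        display_name: Fruits
        rule: {kind: adequacy, lower: 100.0, recommended: 200.0}
      - id: dairy
        display_name: Dairy foods
        rule: {kind: adequacy, lower: 0.0, recommended: 250.0}
      - id: fish
        display_name: Fish
        rule: {kind: adequacy, lower: 0.0, recommended: 28.0}
      - id: legumes
        display_name: Legumes
        rule: {kind: adequacy, lower: 0.0, recommended: 75.0}
      - id: nuts
        display_name: Nuts
        rule: {kind: adequacy, lower: 0.0, recommended: 50.0}
      - id: unsaturated_fats
        display_name: Unsaturated fats
        rule: {kind: adequacy, lower: 20.0, recommended: 40.0}
      - id: red_meat
        display_name: Red meat (unprocessed)
        rule: {kind: moderation, recommended: 14.0, upper: 28.0}
      - id: poultry
        display_name: Chicken and other poultry
        rule: {kind: moderation, recommended: 29.0, upper: 58.0}
      - id: eggs
        display_name: Eggs
        rule: {kind: moderation, recommended: 13.0, upper: 25.0}
      - id: saturated_oils
        display_name: Saturated oils
        rule: {kind: binary_cutoff, cutoff: 11.8}
      - id: added_sugar
        display_name: Added sugar
        rule: {kind: binary_cutoff, cutoff: 31.0}
      - id: processed_meat
        display_name: Processed meat
        rule: {kind: moderation, recommended: 2.0, upper: 4.0}
      - id: alcoholic_beverages
        display_name: Alcoholic beverages
        rule: {kind: zero_tolerance}
  EAT-Lancet:
    per_component_max: 3
    components:
      - id: whole_grains
        display_name: Whole grains
        rule: {kind: ordinal_band, bands: [58.0, 116.0, 232.0], direction: higher_is_better}
      - id: potatoes
        display_name: Potatoes and tubers
        rule: {kind: ordinal_band, bands: [50.0, 75.0, 100.0], direction: lower_is_better}
      - id: vegetables
        display_name: Vegetables
        rule: {kind: ordinal_band, bands: [100.0, 200.0, 300.0], direction: higher_is_better}
      - id: fruits
        display_name: Fruits
        rule: {kind: ordinal_band, bands: [50.0, 100.0, 200.0], direction: higher_is_better}
      - id: dairy
        display_name: Dairy foods
        rule: {kind: ordinal_band, bands: [250.0, 375.0, 500.0], direction: lower_is_better}
      - id: beef_lamb
        display_name: Beef and lamb
        rule: {kind: ordinal_band, bands: [7.0, 10.5, 14.0], direction: lower_is_better}
      - id: pork
        display_name: Pork
        rule: {kind: ordinal_band, bands: [7.0, 10.5, 14.0], direction: lower_is_better}
      - id: poultry
        display_name: Chicken and other poultry
        rule: {kind: ordinal_band, bands: [29.0, 43.5, 58.0], direction: lower_is_better}
      - id: eggs
        display_name: Eggs
        rule: {kind: ordinal_band, bands: [13.0, 19.0, 25.0], direction: lower_is_better}
      - id: fish
        display_name: Fish
        rule: {kind: ordinal_band, bands: [7.0, 14.0, 28.0], direction: higher_is_better}
      - id: legumes
        display_name: Legumes
        rule: {kind: ordinal_band, bands: [18.75, 37.5, 75.0], direction: higher_is_better}
      - id: nuts
        display_name: Nuts
        rule: {kind: ordinal_band, bands: [12.5, 25.0, 50.0], direction: higher_is_better}
      - id: unsaturated_fats
        display_name: Unsaturated / added fats
        rule: {kind: ordinal_band, bands: [10.0, 20.0, 40.0], direction: higher_is_better}
      - id: added_sugar
        display_name: Added sugar
        rule: {kind: ordinal_band, bands: [31.0, 46.5, 62.0], direction: lower_is_better}
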