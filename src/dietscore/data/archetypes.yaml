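# Default regional dietary archetypes for the synthetic survey generator.
#
# Means are mean adult intakes in g/day per source category, chosen to
# caricature four European regional eating patterns: a Mediterranean
# pattern rich in vegetables, fruit, fish, legumes and olive oil; a
# Western pattern high in meat, dairy and sweetened products; an Eastern
# pattern high in pork, potatoes and sugar; and a Northern pattern high
# in whole grains and dairy. They are illustrative, not calibrated to
# any survey.
#
# gender_multipliers scale a category's mean for the female/male strata
# (the total stratum uses 1.0); defaults mirror the common qualitative
# pattern of higher meat/alcohol intake in men and higher fruit and
# vegetable intake in women.
version: 1
default_cv: 0.15
gender_multipliers:
  vegetables: {female: 1.10, male: 0.90}
  fruits: {female: 1.10, male: 0.90}
  dairy: {female: 0.95, male: 1.05}
  beef: {female: 0.85, male: 1.20}
  lamb: {female: 0.85, male: 1.20}
  pork: {female: 0.85, male: 1.20}
  sausages: {female: 0.85, male: 1.20}
  ham: {female: 0.85, male: 1.20}
  poultry: {female: 0.85, male: 1.20}
  sweets: {female: 1.05, male: 0.95}
  soft_drinks: {female: 0.90, male: 1.20}
  alcoholic_beverages: {female: 0.60, male: 1.50}
archetypes:
  mediterranean:
    whole_grain_cereals: 90
    potatoes: 60
    vegetables: 320
    fruits: 280
    dairy: 180
    beef: 25
    lamb: 8
    pork: 15
    sausages: 10
    ham: 12
    poultry: 35
    eggs: 20
    fish: 60
    legumes: 45
    nuts: 18
    vegetable_oils: 45
    butter: 5
    sweets: 30
    soft_drinks: 150
    alcoholic_beverages: 120
  western:
    whole_grain_cereals: 60
    potatoes: 90
    vegetables: 170
    fruits: 140
    dairy: 280
    beef: 45
    lamb: 4
    pork: 35
    sausages: 25
    ham: 18
    poultry: 45
    eggs: 22
    fish: 25
    legumes: 10
    nuts: 8
    vegetable_oils: 25
    butter: 15
    sweets: 50
    soft_drinks: 250
    alcoholic_beverages: 180
  eastern:
    whole_grain_cereals: 70
    potatoes: 140
    vegetables: 190
    fruits: 120
    dairy: 200
    beef: 20
    lamb: 2
    pork: 60
    sausages: 40
    ham: 15
    poultry: 40
    eggs: 28
    fish: 15
    legumes: 18
    nuts: 5
    vegetable_oils: 20
    butter: 18
    sweets: 60
    soft_drinks: 220
    alcoholic_beverages: 160
  northern:
    whole_grain_cereals: 140
    potatoes: 100
    vegetables: 150
    fruits: 110
    dairy: 350
    beef: 35
    lamb: 3
    pork: 30
    sausages: 20
    ham: 10
    poultry: 30
    eggs: 18
    fish: 45
    legumes: 8
    nuts: 6
    vegetable_oils: 22
    butter: 16
    sweets: 45
    soft_drinks: 180
    alcoholic_beverages: 140
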