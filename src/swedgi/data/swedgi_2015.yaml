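# Default reference levels for the 12 components of the Swedish dietary
# guideline index, following the 2015 food-based dietary guidelines of the
# Swedish National Food Agency.
#
# NOTE: these g/day targets are package defaults, not calibrated constants.
# The guideline texts state several recommendations per week or as energy
# percentages; the conversions used here (grams/day equivalents, and per-MJ
# levels at a 2000 kcal = 8.37 MJ reference intake) are documented in
# docs/methods.md and can be overridden with a user YAML of the same shape.
components:
  - name: fruits_berries
    direction: encourage
    basis: grams_per_day
    recommended_level: 250.0          # half of the 500 g/day fruit-and-vegetable target
    recommended_level_per_mj: 29.9
    source_fields: [fruits_berries]
    scoring: proportional_5level
  - name: vegetables
    direction: encourage
    basis: grams_per_day
    recommended_level: 250.0
    recommended_level_per_mj: 29.9
    source_fields: [vegetables]
    scoring: proportional_5level
  - name: legumes
    direction: encourage
    basis: grams_per_day
    recommended_level: 50.0
    recommended_level_per_mj: 6.0
    source_fields: [legumes]
    scoring: proportional_5level
  - name: nuts_seeds
    direction: encourage
    basis: grams_per_day
    recommended_level: 30.0
    recommended_level_per_mj: 3.6
    source_fields: [nuts_seeds]
    scoring: proportional_5level
  - name: whole_grains
    direction: encourage
    basis: grams_per_day
    recommended_level: 70.0           # women's level; 90 g/day for men in the guideline text
    recommended_level_per_mj: 8.4
    source_fields: [whole_grains]
    scoring: proportional_5level
  - name: oil_dressing
    direction: encourage
    basis: grams_per_day
    recommended_level: 10.0
    recommended_level_per_mj: 1.2
    source_fields: [oil_dressing]
    scoring: proportional_5level
  - name: fish_shellfish
    direction: encourage
    basis: grams_per_day
    recommended_level: 50.0           # 2-3 servings/week as a daily-gram equivalent
    recommended_level_per_mj: 6.0
    source_fields: [fish_shellfish]
    scoring: proportional_5level
  - name: red_processed_meat
    direction: restrict
    basis: grams_per_day
    recommended_level: 71.4           # 500 g/week
    recommended_level_per_mj: 8.5
    source_fields: [red_processed_meat]
    scoring: proportional_5level
  - name: high_fat_dairy
    direction: restrict
    basis: grams_per_day
    recommended_level: 50.0
    recommended_level_per_mj: 6.0
    source_fields: [high_fat_dairy]
    scoring: proportional_5level
  - name: added_sugar
    direction: restrict
    basis: grams_per_day
    recommended_level: 50.0           # ~10 E% at the 2000 kcal reference intake
    recommended_level_per_mj: 6.0
    source_fields: [sucrose, fructose, glucose, fruits_berries, vegetables, juice]
    derived: added_sugar
    scoring: proportional_5level
  - name: alcohol
    direction: restrict
    basis: grams_per_day
    recommended_level: 10.0
    recommended_level_per_mj: 1.2
    source_fields: [alcohol]
    scoring: proportional_5level
  - name: salt
    direction: restrict
    basis: grams_per_MJ               # always energy-standardized, as in the index definition
    recommended_level: 0.72           # 6 g/day at the 8.37 MJ reference intake
    recommended_level_per_mj: 0.72
    source_fields: [salt]
    scoring: salt_composite
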