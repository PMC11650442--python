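# Modified reference levels anticipating the NNR2023-aligned update of the
# Swedish food-based dietary guidelines: less red/processed meat, free sugar
# instead of added sugar (lower limit), more vegetables and whole grains.
# Components not listed as changed keep their 2015 defaults.  These values
# are package defaults, not calibrated constants (see docs/methods.md).
components:
  - name: fruits_berries
    direction: encourage
    basis: grams_per_day
    recommended_level: 250.0
    recommended_level_per_mj: 29.9
    source_fields: [fruits_berries]
    scoring: proportional_5level
  - name: vegetables
    direction: encourage
    basis: grams_per_day
    recommended_level: 300.0          # raised per NNR2023 emphasis on vegetables
    recommended_level_per_mj: 35.8
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
    recommended_level: 90.0           # raised per NNR2023
    recommended_level_per_mj: 10.8
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
    recommended_level: 50.0
    recommended_level_per_mj: 6.0
    source_fields: [fish_shellfish]
    scoring: proportional_5level
  - name: red_processed_meat
    direction: restrict
    basis: grams_per_day
    recommended_level: 50.0           # 350 g/week per NNR2023
    recommended_level_per_mj: 6.0
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
    recommended_level: 40.0           # free-sugar limit, stricter than added sugar
    recommended_level_per_mj: 4.8
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
    basis: grams_per_MJ
    recommended_level: 0.72
    recommended_level_per_mj: 0.72
    source_fields: [salt]
    scoring: salt_composite
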