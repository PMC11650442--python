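"""Score the Swedish dietary guideline index for a few hand-written diets.

Builds a three-participant diet table, scores all 12 components with the
shipped 2015 guideline configuration, and prints the component points, the
0-48 total and the adherence category (1 = poorest, 5 = best).
"""

import pandas as pd

import swedgi as sg

diet = pd.DataFrame([
    # a diet close to the guidelines
    dict(pid="good", fruits_berries=240, vegetables=260, legumes=45, nuts_seeds=25,
         whole_grains=65, oil_dressing=9, fish_shellfish=55, red_processed_meat=60,
         high_fat_dairy=30, juice=50, alcohol=5, sucrose=30, fructose=20, glucose=10,
         salt=5.5, fibre=28, energy=2100, salts_at_table=False),
    # a mixed diet
    dict(pid="mixed", fruits_berries=120, vegetables=150, legumes=10, nuts_seeds=5,
         whole_grains=40, oil_dressing=3, fish_shellfish=30, red_processed_meat=100,
         high_fat_dairy=80, juice=150, alcohol=15, sucrose=45, fructose=25, glucose=15,
         salt=8.0, fibre=18, energy=2400, salts_at_table=False),
    # far from every guideline
    dict(pid="poor", fruits_berries=20, vegetables=30, legumes=0, nuts_seeds=0,
         whole_grains=5, oil_dressing=0, fish_shellfish=5, red_processed_meat=180,
         high_fat_dairy=150, juice=300, alcohol=35, sucrose=80, fructose=30, glucose=20,
         salt=11.0, fibre=9, energy=2600, salts_at_table=True),
])

scores = sg.compute_swedgi(diet)  # default: 2015 config, absolute intakes
print(scores.to_string(index=False))
print()
total = scores.set_index("pid")["total"]
print(f"Totals span {total.min()}-{total.max()} of the possible 0-48; each of the")
print("12 components contributes 0-4 points, 4 meaning the guideline is met.")

# the added-sugar intermediate the sugar component is scored on
for _, row in diet.iterrows():
    print(f"added sugar for {row['pid']}: {sg.derive_added_sugar(row):.1f} g/day")
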