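# swedgi

Diet quality, gut-microbial diversity and the metabolic syndrome — a tested
analysis pipeline for diet–microbiome epidemiology.

`swedgi` implements, as reusable library code:

* **SweDGI**, a Swedish dietary guideline index: 12 food-based guideline
  components (7 encouraged, 5 restricted), each scored 0–4 by proportional
  deviation from its recommended level, summed to 0–48 and binned into five
  adherence categories.  Includes the added-sugar derivation
  `max(0, sugars − 0.10·fruit − 0.03·vegetables − 0.08·juice)`, the
  two-criterion salt component, an energy-standardized (g/MJ) variant and an
  NNR2023-aligned configuration.  Reference levels are YAML configuration.
* **Metabolic syndrome classification** by the harmonized consensus rule:
  ≥ 3 of 5 criteria (BP ≥ 130/85 mmHg, glucose ≥ 5.6 mmol/L, TG ≥ 1.7
  mmol/L, HDL ≤ 1.29/1.03 mmol/L W/M, waist ≥ 80/94 cm W/M), with
  medication overrides.
* **Rarefied Shannon α-diversity**: species count tables are downsized to a
  fixed depth (default 210,430 reads) by sampling without replacement, then
  H = −Σ pᵢ ln pᵢ is computed per sample, with rank-based quantile groups.
* **The exclusion cascade** (missing diet, implausible energy, diabetes,
  unknown MetS, missing metagenome, antibiotics) with a conserving audit
  trail.
* **The model battery**: linear and logistic trend models across exposure
  categories with nested covariate tiers, mutual adjustment of index
  components, multiplicative interaction tests, and 3×3 joint-effect OR
  grids.
* **A synthetic cohort generator** that plants known effects
  (diet→diversity slope, diet/diversity→MetS log-odds, confounding) so
  every stage is testable without any external data.

## A worked example

```python
import swedgi as sg
from swedgi.models import ModelSpec

cohort = sg.generate_cohort(sg.SimConfig(n_participants=6000, seed=20))
table, audit = sg.build_analysis_table(cohort, seed=20)
table = table.assign(mets=table.mets.astype(float))

lin = sg.fit_linear_trend(table, ModelSpec(outcome="shannon",
                                           exposure="swedgi_category"))
grids = sg.joint_effect(table, "swedgi_total", "shannon")
```

Running `python examples/05_full_analysis.py` (which does exactly this)
prints:

```
analysis sample n = 6000; MetS prevalence = 33.3%

Shannon per index category: beta = +0.0235 (95% CI +0.0163, +0.0308), p-trend = 2.33e-10  [planted +0.0240]
MetS OR per index category = 0.907, category 5 vs 1 = 0.66  [planted 5-vs-1 OR 0.59]
MetS OR per Shannon quintile = 0.864, quintile 5 vs 1 = 0.55  [planted 0.53]
diet x diversity interaction on MetS: p = 0.29 (none planted)

OR grid vs (low diet quality, low diversity) reference (rows: index tertile, cols: Shannon tertile):
      1     2     3
1  1.00  0.74  0.66
2  1.05  0.72  0.58
3  0.75  0.65  0.42
```

Reading it: each step up the five diet-adherence categories raises the
Shannon index by ≈ 0.024 nats and lowers the odds of MetS; diversity carries
an independent inverse association; and the lowest MetS odds (OR 0.42) sit
in the cell combining high adherence with high diversity — the recovered
values bracket what was planted.  The other scripts in `examples/` walk
through each capability (index scoring, MetS classification, rarefied
diversity, the exclusion cascade) on small hand-written inputs.

A thin CLI mirrors the stages for file-to-file use:

```sh
swedgi simulate --n 1000 --seed 1 --outdir cohort/
swedgi score --diet cohort/diet.tsv --out scores.tsv
swedgi mets --clinical cohort/clinical.tsv --out mets.tsv
swedgi diversity --abundance cohort/abundance.tsv --depth 210430 --seed 1 --out div.tsv
swedgi filter --diet cohort/diet.tsv --clinical cohort/clinical.tsv --audit audit.tsv --outdir filtered/
```

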