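"""The full analysis on a synthetic cohort: diet index -> diversity -> MetS.

Generates a cohort with the default planted effects (Shannon +0.024 per
index category; MetS OR ~0.59 for category 5 vs 1 and ~0.53 for Shannon
quintile 5 vs 1), runs the whole pipeline, and fits the model battery:
linear trend, logistic trends, interaction, and the 3x3 joint-effect grid.
"""

import numpy as np

import swedgi as sg
from swedgi.models import ModelSpec

cohort = sg.generate_cohort(sg.SimConfig(n_participants=6000, seed=20))
table, audit = sg.build_analysis_table(cohort, seed=20)
table = table.assign(mets=table.mets.astype(float))
print(f"analysis sample n = {len(table)}; MetS prevalence = {table.mets.mean():.1%}")

# Shannon across index categories (linear model, main covariate tier)
lin = sg.fit_linear_trend(table, ModelSpec(outcome="shannon", exposure="swedgi_category"))
print(f"\nShannon per index category: beta = {lin.estimate:+.4f} "
      f"(95% CI {lin.ci95[0]:+.4f}, {lin.ci95[1]:+.4f}), p-trend = {lin.p_trend:.2e}"
      f"  [planted {cohort.truth['diet_diversity_slope']:+.4f}]")

# MetS across index categories (logistic, adjusted for Shannon quintile)
logi = sg.fit_logistic(table, ModelSpec(outcome="mets", exposure="swedgi_category",
                                        extra_covariates=["shannon_quintile"]))
or5 = logi.extras["per_category"][5][0]
print(f"MetS OR per index category = {logi.estimate:.3f}, category 5 vs 1 = {or5:.2f}"
      f"  [planted 5-vs-1 OR {np.exp(4 * cohort.truth['mets_log_or_per_category']):.2f}]")

# MetS across Shannon quintiles (logistic, adjusted for the index)
logq = sg.fit_logistic(table, ModelSpec(outcome="mets", exposure="shannon_quintile",
                                        extra_covariates=["swedgi_category"]))
orq5 = logq.extras["per_category"][5][0]
print(f"MetS OR per Shannon quintile = {logq.estimate:.3f}, quintile 5 vs 1 = {orq5:.2f}"
      f"  [planted {np.exp(4 * cohort.truth['mets_log_or_per_shannon_quintile']):.2f}]")

# no interaction was planted between diet quality and diversity
p_int = sg.test_interaction(table, ModelSpec(outcome="mets", exposure="swedgi_category"),
                            "shannon_quintile", "swedgi_category")
print(f"diet x diversity interaction on MetS: p = {p_int:.2f} (none planted)")

# joint effect: tertiles of index total x tertiles of Shannon
grids = sg.joint_effect(table, "swedgi_total", "shannon", covariate_tier="main")
print("\nOR grid vs (low diet quality, low diversity) reference "
      "(rows: index tertile, cols: Shannon tertile):")
print(grids["or_grid"].round(2).to_string())
print("\nThe (3,3) cell - high adherence AND high diversity - shows the lowest")
print("odds of MetS, the joint-effect pattern the models are built to expose.")
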