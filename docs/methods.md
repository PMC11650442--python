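# Methods

This note documents the models and procedures implemented in `swedgi`, the
choices made where the design was genuinely open, and what the built-in
simulations do and do not demonstrate.

## The dietary guideline index

The index measures adherence to 12 Swedish food-based dietary guidelines:
seven encouraged intakes (fruits and berries, vegetables, legumes, nuts and
seeds, whole grains, oil dressings, fish and shellfish) and five restricted
ones (red/processed meat, high-fat dairy, added sugar, alcohol, salt).
Each component is scored 0–4 on the relative deviation *d* from its
recommended level *R*:

    encouraged:  d = (R − intake) / R
    restricted:  d = (intake − R) / R

    d ≤ 0 → 4    0 < d < 0.25 → 3    0.25 ≤ d < 0.50 → 2
    0.50 ≤ d < 0.75 → 1    d ≥ 0.75 → 0

The brackets are half-open on the left ("< 25 %" strict), so a deviation of
exactly 25 % scores 2; this makes the partition exhaustive and disjoint.
Restricted foods are scored one-sidedly: any intake at or below the maximum
scores 4, because those guidelines are stated as ceilings.  Added sugar is
derived before scoring as

    max(0, sucrose + fructose + glucose
           − 0.10·fruits_berries − 0.03·vegetables − 0.08·juice)

(the subtracted terms estimate naturally occurring sugars; negative grams
are physically meaningless and clamped to zero).  Salt is a two-criterion
composite: energy-standardized salt intake scored 0–3 with the proportional
brackets compressed to three steps (d ≤ 0 → 3, < 25 % → 2, 25–50 % → 1,
≥ 50 % → 0), plus 1 point for not salting at the table.  Salt is always
compared per MJ, even in the absolute variant, because absolute salt intake
correlates too strongly with total energy to be meaningful.

Component points sum to a 0–48 total, binned into five adherence categories
at the published cutpoints (≤ 18, 19–22, 23–25, 26–29, ≥ 30); an SPSS-style
equal-frequency ntile binning (ties always share a group) is available as an
alternative.

**Reference levels are configuration, not code.**  The exact recommended
levels live in YAML (`swedgi_2015.yaml`, `swedgi_nnr2023.yaml`).  The
shipped values are defaults assembled from the 2015 guidelines' main
statements (e.g. 500 g/day fruit + vegetables split evenly, 500 g/week red
and processed meat, ~10 E% added sugar, 6 g/day salt) with weekly or
energy-percent recommendations converted to g/day at a 2000 kcal
(8.37 MJ) reference intake; they are deliberately overridable and should be
re-specified when exact study thresholds are available.  The NNR2023
configuration lowers the meat and (free-)sugar limits and raises the
vegetable and whole-grain targets.  The per-MJ variant divides every intake
by reported energy (1 kcal = 4.1868 kJ, thermochemical calorie) and uses
per-MJ reference levels; it is invariant to rescaling a participant's whole
diet.  Participants missing any component input are excluded from scoring
(complete case) with a log entry rather than imputed.

## MetS classification

The harmonized IDF/AHA/NHLBI consensus rule: MetS = at least 3 of
{BP ≥ 130/85 mmHg or antihypertensive treatment; fasting glucose
≥ 5.6 mmol/L; TG ≥ 1.7 mmol/L or lipid-lowering treatment; HDL ≤ 1.29 (W) /
1.03 (M) mmol/L; waist ≥ 80 (W) / 94 (M) cm}.  All comparisons are
inclusive at the cutpoints.  The consensus statement counts lipid-lowering
treatment toward "dyslipidaemia" without splitting the two lipid criteria,
so by default medication satisfies both TG and low-HDL;
`lipid_med_affects_hdl=False` restricts it to TG.  Missing measured inputs
make a participant unclassifiable (excluded downstream), never imputed;
missing medication flags are read as "no reported treatment".

## Rarefied Shannon diversity

Samples are downsized to a fixed depth (default 210,430 reads) by a single
multivariate-hypergeometric draw per sample — sampling reads without
replacement from the observed counts — and the Shannon index
H = −Σ pᵢ ln pᵢ (natural log) is computed on the downsized counts.  One
draw per sample, not an average over draws, with the seed recorded by the
caller, keeps the procedure reproducible and honest about its Monte Carlo
error.  Samples shallower than the depth are dropped, not scaled, because
without-replacement sampling is undefined below depth.  Quantile groups
(quintiles for trend models, tertiles for joint-effect models) are
rank-based with ties sharing a group; all-identical values raise an error
rather than silently producing one group.

## Exclusion cascade

Ordered participant-local predicates with a full audit trail: missing diet
→ implausible energy (women < 500 or > 5,000 kcal/day, men < 550 or
> 6,000; strict comparisons, so a woman reporting exactly 500 kcal is kept)
→ known diabetes (questionnaire flag only, no glucose-based inference) →
unknown MetS status → (for microbiome analyses) missing metagenomic data;
an antibiotics-in-the-last-6-months step supports sensitivity analyses.
Each participant is excluded at its first failing step, so per-step counts
depend on order but the final kept set never does.

## Association models

* **Trend tests** enter the ordered category index (1–5, or quantile group)
  as a single continuous covariate; "per category" effects are this
  coefficient.  Per-category indicator fits against the lowest category are
  emitted alongside (least-squares adjusted means for linear models,
  Wald-CI odds ratios for logistic ones).
* **Covariate tiers** are nested: basic (age, sex, site, energy) ⊂ main
  (+ smoking, physical activity, education) ⊂ main+{BMI, fibre, Shannon,
  index category}.  Categorical covariates enter as indicators; every fit is
  complete-case, so n varies by model.
* **Logistic fits** use the binomial GLM (IRLS, max 100 iterations,
  deviance tolerance 1e-8); non-convergence and suspected separation
  (|coefficient| > 30) raise instead of returning garbage.  On any 2×2
  collapse the fitted OR equals the contingency cross-product ratio (tested
  to 1e-6).
* **Interactions** are Wald tests on the product of the two continuously
  coded factors added to the main-effects model.
* **Joint effects** cross-classify two tertiled exposures into one logistic
  model with 8 indicators against the (low, low) cell.
* All p-values are two-sided Wald; CIs are estimate ± 1.96 SE on the link
  scale, exponentiated for ORs.  No multiple-testing correction is applied
  (deliberately, matching common practice in this literature); the
  0.05/0.10 significance-vs-tendency convention is exposed as
  `significance_label`.

## The synthetic cohort generator

The generator emulates a middle-aged (50–64 y) Swedish screening cohort at
the food-group level.  What it reproduces: right-skewed log-normal intakes
with women closer to the recommendations than men (index means ≈ 24 vs 20,
matching the observed sex gap), component-level adherence fractions from a
few percent (nuts, legumes, oil dressings, salt) to ~70 % (added sugar),
index totals averaging ≈ 22 (SD ≈ 5) spread over all five categories, a MetS
prevalence near 31 %, Shannon values near 4.1 nats, and configurable
confounding of both outcomes by sex, age and smoking.  What it does not
emulate: item-level questionnaire structure, measurement error and
systematic misreporting, within-person day-to-day variation, taxonomic
realism of the species pool, site effects, or any missingness mechanism
beyond missing-completely-at-random.  Passing recovery tests therefore
demonstrates that the estimators are correct under the assumed model — not
that the assumed model captures real dietary data.

Mechanics:

1. **Diet first.**  Intakes are log-normal per food group with sex-specific
   medians (fractions of each recommended level) and a small age trend; the
   sugar fields are constructed so the added-sugar formula recovers the
   intended added-sugar amount exactly.  The generated diet is scored with
   the shipped 2015 configuration to obtain each participant's index
   category — the index is *derived*, never assigned.
2. **Diversity.**  Each participant receives a target Shannon value, linear
   in category (the planted slope, default +0.024/category) plus sex/age
   confounding and N(0, 0.30) noise around a baseline of 4.09 nats (lowered
   automatically when `n_species` cannot support it).  The target is
   converted to a geometric rank-abundance curve pᵢ ∝ e^(−θi) whose entropy
   equals the target (θ solved on a precomputed monotone grid), and counts
   are one multinomial draw at the sample's sequencing depth
   (default 230–300k reads over 150 species).  This gives direct, unbiased
   control of the planted slope; a Dirichlet-shift construction was
   considered and rejected because it controls expected entropy only
   implicitly.
3. **MetS.**  Status is drawn from the planted logistic model
   (baseline prevalence 31 %; default log-ORs ln(0.59)/4 per index category
   and ln(0.53)/4 per Shannon quintile, i.e. the magnitudes such cohorts
   report; confounder effects on top).  The number of satisfied criteria is
   then drawn conditionally on status (3–5 if positive, 0–2 if negative),
   criteria are allocated by weighted sampling, and each clinical value is
   drawn truncated on the correct side of its cutpoint — so the rule-based
   classifier reproduces the planted status exactly.  Medication flags are
   set only where the measurement already satisfies the criterion, so the
   lipid-medication convention cannot change the planted criterion count.
4. **Missingness** is injected MCAR per field (defaults ≈ 4–6 % on smoking,
   physical activity and education, mirroring typical questionnaire
   non-response).

Everything derives from one seeded `numpy` generator in fixed order:
identical configurations give byte-identical tables.  The planted values
are recorded in a `truth` map written alongside the tables.

A hand-built 12-participant toy fixture complements the generator: one
participant per index score band, one per MetS criterion count (0–5), and
exactly one violator of each exclusion rule, with a self-describing
manifest.

## Simulation sizes and calibration checks

The test suite validates the statistical machinery at sizes chosen to keep
a full run within a few minutes on one CPU:

* **Parameter recovery** — 50 cohorts of n = 10,000 under the default
  generator settings; the recovery models mirror the generative structure
  (category and Shannon-quintile effects fitted jointly with the
  confounders).  Each planted value (Shannon slope, both MetS log-ORs) must
  land within 2 SE of its estimate in at least 47 of 50 replicates.  Note
  that for a perfectly calibrated estimator 2 SE covers ≈ 95.4 %, so the
  ≥ 47/50 requirement itself passes only ≈ 80 % of seed batches per
  parameter; it is a deliberately strict bar.
* **Null calibration** — 200 cohorts of n = 1,000 with every planted effect
  zero (confounding retained); the Shannon trend test and the
  diet × diversity interaction test must reject at the nominal 5 % rate
  (accepted band 3–7 %).  A band this tight on 200 draws has material
  Monte Carlo noise: even an exactly nominal test falls outside it ~15 % of
  the time.  Uniformity of the p-value distributions is additionally
  diagnosable via the examples.
* **Rarefaction law** — the marginal distribution of downsized counts is
  checked against the hypergeometric pmf by a χ² goodness-of-fit over
  10,000 draws, and subsampling unbiasedness over 200 seeds.

## Known limitations

* Reference intake levels are package defaults, not study-calibrated
  thresholds; results at the component level depend on them.
* Whether lipid-lowering treatment should satisfy the HDL criterion is
  genuinely ambiguous in the consensus wording; both conventions are
  implemented, defaulting to "both lipid criteria".
* Quantile groups are computed on the analysis sample after exclusions;
  computing them before exclusions would shift group boundaries slightly.
* The joint-effect model conditions on non-empty cells and raises
  otherwise; very sparse strata need coarser binning.
* Logistic effects are non-collapsible: marginal and covariate-adjusted
  odds ratios differ by construction, so recovery checks must (and do)
  fit the generative adjustment set.
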