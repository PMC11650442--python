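"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a middle-aged Swedish screening cohort: per-
participant food and nutrient intakes (log-normal, right-skewed, women
closer to the recommendations than men), a clinical table with metabolic-
syndrome inputs, and a species-by-sample metagenomic count table.  Three
effects can be planted and are recorded in the cohort's ``truth`` map:

* ``diet_diversity_slope`` - expected change in the Shannon index per
  diet-index category;
* ``mets_log_or_per_category`` - log-odds of MetS per diet-index category;
* ``mets_log_or_per_shannon_quintile`` - log-odds of MetS per Shannon
  quintile;

plus configurable confounding of both outcomes by sex, age and smoking.

Mechanics, briefly: diet is drawn first and scored with the shipped 2015
guideline configuration; each participant then receives a target Shannon
value (linear in their diet category plus confounders and noise), which is
converted to a geometric rank-abundance curve whose entropy equals the
target, and read counts are a multinomial draw from that curve.  MetS status
is drawn from the planted logistic model, and the clinical criterion values
are then drawn conditionally on the planted status (truncated on the correct
side of each cutpoint), so the rule-based classifier reproduces the planted
outcome exactly.  Medication flags are only set where the measurement
already satisfies the criterion, so they never alter the planted count of
criteria.  Missingness is injected completely at random at configurable
per-field rates.

Everything is drawn from one seeded generator in a fixed order, so identical
configurations give byte-identical cohorts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit

from .cohort import SyntheticCohort
from .diversity import AbundanceTable, quantile_groups
from .guidelines import load_guidelines
from .index import KCAL_TO_MJ, compute_swedgi

__all__ = ["SimConfig", "generate_cohort", "make_toy_fixture"]

# Default planted effects mirror the magnitudes reported for this kind of
# cohort: Shannon +0.024 per index category, OR 0.59 for category 5 vs 1
# (= ln 0.59 / 4 per category), OR 0.53 for Shannon quintile 5 vs 1, and a
# baseline MetS prevalence of 31 %.
DEFAULT_SHANNON_SLOPE = 0.024
DEFAULT_METS_LOG_OR_PER_CATEGORY = math.log(0.59) / 4
DEFAULT_METS_LOG_OR_PER_QUINTILE = math.log(0.53) / 4

DEFAULT_CONFOUNDERS = {
    "female_on_mets": -0.35,
    "age_on_mets": 0.02,
    "current_smoker_on_mets": 0.30,
    "female_on_shannon": 0.05,
    "age_on_shannon": 0.002,
}

DEFAULT_MISSINGNESS = {"smoking": 0.041, "physical_activity": 0.057, "education": 0.034}

_BASE_SHANNON = 4.09
_SHANNON_SD = 0.30
_BASE_METS_PREVALENCE = 0.31

# per-food intake model: median intake as a fraction of the recommended
# level (men, women) and log-scale SD; chosen to reproduce the typical
# right-skew of FFQ data and published adherence percentages (see
# docs/methods.md)
_FOOD_RATIOS = {
    "fruits_berries": (0.35, 0.55, 0.85),
    "vegetables": (0.45, 0.70, 0.75),
    "legumes": (0.10, 0.15, 1.10),
    "nuts_seeds": (0.10, 0.14, 1.10),
    "whole_grains": (0.35, 0.45, 0.90),
    "oil_dressing": (0.12, 0.16, 1.00),
    "fish_shellfish": (0.62, 0.58, 0.90),
    "red_processed_meat": (1.05, 0.80, 0.55),
    "high_fat_dairy": (0.90, 0.75, 0.80),
    "added_sugar": (0.82, 0.72, 0.45),
    "alcohol": (1.00, 0.70, 0.95),
    "salt": (1.65, 1.50, 0.28),
}

_CRITERIA = ("waist", "bp", "glucose", "tg", "hdl")
# relative frequency with which each criterion is among those met
_CRITERION_WEIGHTS = np.array([0.27, 0.28, 0.17, 0.15, 0.13])


class SimConfig(BaseModel):
    """Configuration of one synthetic cohort."""

    n_participants: int = Field(1000, ge=1)
    seed: int = 0
    frac_female: float = Field(0.53, ge=0.0, le=1.0)
    diet_diversity_slope: float = DEFAULT_SHANNON_SLOPE
    mets_log_or_per_category: float = DEFAULT_METS_LOG_OR_PER_CATEGORY
    mets_log_or_per_shannon_quintile: float = DEFAULT_METS_LOG_OR_PER_QUINTILE
    confounder_strengths: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_CONFOUNDERS))
    n_species: int = Field(150, ge=2)
    reads_per_sample_range: tuple[int, int] = (230_000, 300_000)
    missingness_rates: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    shannon_sd: float = Field(_SHANNON_SD, gt=0.0)
    base_shannon: float = Field(_BASE_SHANNON, gt=0.0)
    mets_prevalence: float = Field(_BASE_METS_PREVALENCE, gt=0.0, lt=1.0)

    @field_validator("reads_per_sample_range")
    @classmethod
    def _ordered_range(cls, v):
        lo, hi = v
        if lo < 1 or lo > hi:
            raise ValueError(f"reads_per_sample_range must satisfy 1 <= low <= high, got {v}")
        return v

    @field_validator("missingness_rates")
    @classmethod
    def _rates_are_proportions(cls, v):
        for k, r in v.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness_rates[{k!r}] must be in [0, 1], got {r}")
        return v


# ------------------------------------------------------- entropy targets --

def _geometric_entropy_grid(n_species: int, n_grid: int = 800):
    """Entropy of the truncated geometric rank-abundance curve on a theta grid."""
    theta = np.concatenate([[0.0], np.geomspace(1e-5, 6.0, n_grid)])
    ranks = np.arange(n_species)
    w = np.exp(-np.outer(theta, ranks))
    p = w / w.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log(p), 0.0)).sum(axis=1)
    return theta, h


def _theta_for_entropy(targets: np.ndarray, n_species: int) -> np.ndarray:
    theta, h = _geometric_entropy_grid(n_species)
    # h is decreasing in theta; np.interp wants increasing x
    return np.interp(targets, h[::-1], theta[::-1])


def _halfnorm(rng, scale, size):
    return np.abs(rng.normal(0.0, scale, size))


# ------------------------------------------------------------- generator --

def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one cohort (diet, clinical and abundance tables plus truth)."""
    if not isinstance(config, SimConfig):
        config = SimConfig(**config)
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    conf = {**DEFAULT_CONFOUNDERS, **config.confounder_strengths}

    pids = [f"P{i:06d}" for i in range(1, n + 1)]
    female = rng.random(n) < config.frac_female
    sex = np.where(female, "female", "male")
    age = np.round(rng.uniform(50, 65, n), 1)
    site = rng.choice(["Malmo", "Uppsala"], size=n, p=[0.55, 0.45])
    smoking = rng.choice(["never", "ex", "current"], size=n, p=[0.45, 0.35, 0.20])
    physical_activity = rng.choice(
        ["sedentary", "moderate", "regular_moderate", "intensive"],
        size=n, p=[0.12, 0.45, 0.31, 0.12],
    )
    education = rng.choice(
        ["incomplete_primary", "primary", "upper_secondary", "university"],
        size=n, p=[0.04, 0.18, 0.33, 0.45],
    )
    born_in_sweden = rng.choice(["yes", "no"], size=n, p=[0.81, 0.19])

    energy = np.exp(rng.normal(np.where(female, np.log(1950.0), np.log(2400.0)), 0.22))
    energy = np.round(energy, 0)

    specs = {s.name: s for s in load_guidelines("swedgi_2015")}
    age_shift = 0.004 * (age - 57.0)  # older participants eat slightly better

    intakes: dict[str, np.ndarray] = {}
    for name, (med_m, med_f, sigma) in _FOOD_RATIOS.items():
        mu = np.where(female, np.log(med_f), np.log(med_m))
        encouraged = specs[name].direction == "encourage" if name in specs else False
        ratio = np.exp(rng.normal(mu + (age_shift if encouraged else 0.0), sigma))
        intakes[name] = ratio

    diet = pd.DataFrame({"pid": pids})
    for name in (
        "fruits_berries", "vegetables", "legumes", "nuts_seeds",
        "whole_grains", "oil_dressing", "fish_shellfish",
        "red_processed_meat", "high_fat_dairy",
    ):
        diet[name] = np.round(intakes[name] * specs[name].recommended_level, 1)
    diet["juice"] = np.round(np.exp(rng.normal(np.log(40.0), 1.0, n)), 1)
    diet["alcohol"] = np.round(intakes["alcohol"] * specs["alcohol"].recommended_level, 1)
    # back out the sugar fields so the added-sugar formula recovers the target
    added_target = intakes["added_sugar"] * specs["added_sugar"].recommended_level
    diet["fructose"] = np.round(0.10 * diet["fruits_berries"], 1)
    diet["glucose"] = np.round(0.03 * diet["vegetables"] + 0.08 * diet["juice"], 1)
    diet["sucrose"] = np.round(added_target, 1)
    diet["salt"] = np.round(
        intakes["salt"] * specs["salt"].recommended_level * energy * KCAL_TO_MJ, 2
    )
    diet["fibre"] = np.round(
        8.0 + 0.12 * diet["whole_grains"] + 0.05 * diet["vegetables"]
        + 0.02 * diet["fruits_berries"] + _halfnorm(rng, 3.0, n), 1
    )
    diet["energy"] = energy
    diet["salts_at_table"] = rng.random(n) < 0.25

    scores = compute_swedgi(diet, specs=list(specs.values()), variant="absolute")
    category = scores.set_index("pid").loc[pids, "category"].to_numpy()

    # --- planted Shannon structure -------------------------------------
    # lower the baseline when few species cannot support it, so targets
    # stay inside the feasible entropy range (0, ln S)
    base = min(config.base_shannon, np.log(config.n_species) - 2.5 * config.shannon_sd)
    h0 = base - conf["female_on_shannon"] * config.frac_female
    h_target = (
        h0
        + config.diet_diversity_slope * (category - 3.0)
        + conf["female_on_shannon"] * female
        + conf["age_on_shannon"] * (age - 57.0)
        + rng.normal(0.0, config.shannon_sd, n)
    )
    h_target = np.clip(h_target, 0.2, np.log(config.n_species) - 0.05)
    shannon_quintile = quantile_groups(pd.Series(h_target), 5).to_numpy() if n >= 5 else np.ones(n, int)

    # --- planted MetS structure ----------------------------------------
    b0 = math.log(config.mets_prevalence / (1.0 - config.mets_prevalence))
    logit = (
        b0
        + config.mets_log_or_per_category * (category - 3.0)
        + config.mets_log_or_per_shannon_quintile * (shannon_quintile - 3.0)
        + conf["female_on_mets"] * (female - config.frac_female)
        + conf["age_on_mets"] * (age - 57.0)
        + conf["current_smoker_on_mets"] * ((smoking == "current") - 0.20)
    )
    mets = rng.random(n) < expit(logit)

    n_met = np.where(
        mets,
        rng.choice([3, 4, 5], size=n, p=[0.55, 0.30, 0.15]),
        rng.choice([0, 1, 2], size=n, p=[0.35, 0.40, 0.25]),
    )
    # which criteria are met: Gumbel-top-k with fixed criterion weights
    keys = np.log(_CRITERION_WEIGHTS) + rng.gumbel(size=(n, 5))
    order = np.argsort(-keys, axis=1)
    rows = np.arange(n)[:, None]
    ranks = np.empty_like(order)
    ranks[rows, order] = np.arange(5)[None, :]
    met = ranks < n_met[:, None]
    met_c = {c: met[:, i] for i, c in enumerate(_CRITERIA)}

    waist_cut = np.where(female, 80.0, 94.0)
    hdl_cut = np.where(female, 1.29, 1.03)
    waist = np.where(
        met_c["waist"],
        waist_cut + rng.exponential(9.0, n),
        np.maximum(62.0, waist_cut - 0.5 - _halfnorm(rng, 9.0, n)),
    )
    u = rng.random(n)  # among bp-positive: 0.60 only sbp, 0.25 both, 0.15 only dbp
    sbp_no = np.maximum(90.0, 127.0 - _halfnorm(rng, 12.0, n))
    dbp_no = np.maximum(55.0, 83.0 - _halfnorm(rng, 7.0, n))
    sbp_yes = 130.0 + rng.exponential(12.0, n)
    dbp_yes = 85.0 + rng.exponential(6.0, n)
    sbp = np.where(met_c["bp"] & (u < 0.85), sbp_yes, sbp_no)
    dbp = np.where(met_c["bp"] & (u >= 0.60), dbp_yes, dbp_no)
    fpg = np.where(
        met_c["glucose"], 5.6 + rng.exponential(0.5, n),
        np.maximum(3.8, 5.59 - _halfnorm(rng, 0.45, n)),
    )
    tg = np.where(
        met_c["tg"], 1.7 + rng.exponential(0.7, n),
        np.maximum(0.45, 1.69 - _halfnorm(rng, 0.40, n)),
    )
    hdl = np.where(
        met_c["hdl"], np.maximum(0.5, hdl_cut - _halfnorm(rng, 0.18, n)),
        hdl_cut + 0.02 + rng.exponential(0.28, n),
    )
    # medication flags only where the measurement already meets the criterion,
    # so overrides never change the planted criterion count
    measured_bp = (sbp >= 130.0) | (dbp >= 85.0)
    antihypertensive_med = measured_bp & (rng.random(n) < 0.35)
    measured_lipids = (tg >= 1.7) & (hdl <= hdl_cut)
    lipid_lowering_med = measured_lipids & (rng.random(n) < 0.25)
    bmi = np.round(np.maximum(16.0, 0.32 * waist - 3.5 + rng.normal(0.0, 1.8, n)), 1)

    clinical = pd.DataFrame(
        {
            "pid": pids,
            "sex": sex,
            "age": age,
            "site": site,
            "smoking": smoking,
            "physical_activity": physical_activity,
            "education": education,
            "born_in_sweden": born_in_sweden,
            "waist": np.round(waist, 1),
            "sbp": np.round(sbp, 1),
            "dbp": np.round(dbp, 1),
            "fpg": np.round(fpg, 2),
            "tg": np.round(tg, 2),
            "hdl": np.round(hdl, 2),
            "antihypertensive_med": antihypertensive_med,
            "lipid_lowering_med": lipid_lowering_med,
            "diabetes": np.zeros(n, dtype=bool),
            "antibiotics_6mo": rng.random(n) < 0.095,
            "bmi": bmi,
            "energy": energy,
        }
    )

    # --- abundance: entropy-targeted geometric curves -------------------
    theta = _theta_for_entropy(h_target, config.n_species)
    ranks_s = np.arange(config.n_species)
    lo, hi = config.reads_per_sample_range
    reads = rng.integers(lo, hi + 1, size=n)
    counts = np.empty((config.n_species, n), dtype=np.int64)
    for i in range(n):
        w = np.exp(-theta[i] * ranks_s)
        counts[:, i] = rng.multinomial(reads[i], w / w.sum())
    abundance = AbundanceTable(
        [f"MGS{j:04d}" for j in range(1, config.n_species + 1)], list(pids), counts
    )

    # --- missingness (MCAR) --------------------------------------------
    for fld, rate in config.missingness_rates.items():
        if rate <= 0:
            continue
        mask = rng.random(n) < rate
        if fld in clinical.columns:
            col = clinical[fld]
            clinical[fld] = col.astype(object).where(~mask, np.nan) if col.dtype == object else col.mask(mask)
        elif fld in diet.columns:
            diet[fld] = diet[fld].mask(mask)
        else:
            raise ValueError(f"missingness_rates names unknown field {fld!r}")

    truth = {
        "diet_diversity_slope": config.diet_diversity_slope,
        "mets_log_or_per_category": config.mets_log_or_per_category,
        "mets_log_or_per_shannon_quintile": config.mets_log_or_per_shannon_quintile,
        "base_shannon": h0,
        "shannon_sd": config.shannon_sd,
        "mets_prevalence": config.mets_prevalence,
        "confounder_strengths": conf,
        "n_participants": n,
        "seed": config.seed,
    }
    return SyntheticCohort(diet=diet, clinical=clinical, abundance=abundance, truth=truth)


# ------------------------------------------------------------ toy fixture --

def make_toy_fixture() -> SyntheticCohort:
    """A fixed, hand-checkable 12-participant cohort.

    Contains one participant per diet-index score band (S1-S5), one per
    count of satisfied MetS criteria (S1-S6 carry 0-5), and exactly one
    violator of each exclusion rule (X_diet, X_energy, X_diab, X_mets,
    X_micro, X_abx).  The ``truth`` map is a manifest of all planted facts.
    """
    specs = {s.name: s for s in load_guidelines("swedgi_2015")}
    energy = 2000.0
    energy_mj = energy * KCAL_TO_MJ
    favour_order = [
        "fruits_berries", "vegetables", "legumes", "nuts_seeds", "whole_grains",
        "oil_dressing", "fish_shellfish", "red_processed_meat", "high_fat_dairy",
        "added_sugar", "alcohol", "salt",
    ]
    encouraged = {
        "fruits_berries", "vegetables", "legumes", "nuts_seeds",
        "whole_grains", "oil_dressing", "fish_shellfish",
    }

    def diet_row(pid: str, n_favourable: int, energy_kcal: float = energy) -> dict:
        fav = set(favour_order[:n_favourable])
        row = {"pid": pid, "energy": energy_kcal, "juice": 0.0, "fibre": 15.0}
        for name in favour_order:
            rec = specs[name].recommended_level
            if name == "added_sugar":
                continue
            if name == "salt":
                ratio = 0.5 if name in fav else 2.0
                row["salt"] = round(ratio * rec * energy_kcal * KCAL_TO_MJ, 3)
                row["salts_at_table"] = name not in fav
            elif name in encouraged:
                row[name] = rec if name in fav else 0.0
            else:
                row[name] = 0.0 if name in fav else 2.0 * rec
        # sugar fields: derived added sugar is exactly 0 (favourable) or 2x limit
        natural = 0.10 * row["fruits_berries"] + 0.03 * row["vegetables"]
        if "added_sugar" in fav:
            row.update(sucrose=0.0, fructose=0.0, glucose=0.0)  # derived sugar 0 -> 4 points
        else:
            row.update(
                sucrose=round(2.0 * specs["added_sugar"].recommended_level + natural, 2),
                fructose=0.0,
                glucose=0.0,
            )
        return row

    # clinical values well inside / outside each cutpoint
    def clinical_row(pid: str, sex: str, n_met: int, **over) -> dict:
        hdl_cut = 1.29 if sex == "female" else 1.03
        waist_cut = 80.0 if sex == "female" else 94.0
        met = set(_CRITERIA[:n_met])
        row = {
            "pid": pid,
            "sex": sex,
            "age": 57.0,
            "site": "Malmo",
            "smoking": "never",
            "physical_activity": "moderate",
            "education": "university",
            "born_in_sweden": "yes",
            "waist": waist_cut + 10.0 if "waist" in met else waist_cut - 10.0,
            "sbp": 140.0 if "bp" in met else 118.0,
            "dbp": 88.0 if "bp" in met else 72.0,
            "fpg": 6.2 if "glucose" in met else 5.0,
            "tg": 2.2 if "tg" in met else 1.1,
            "hdl": hdl_cut - 0.2 if "hdl" in met else hdl_cut + 0.3,
            "antihypertensive_med": False,
            "lipid_lowering_med": False,
            "diabetes": False,
            "antibiotics_6mo": False,
            "bmi": 26.0,
            "energy": energy,
        }
        row.update(over)
        return row

    band_favourable = {"S1": 4, "S2": 5, "S3": 6, "S4": 7, "S5": 12, "S6": 5}
    sexes = {"S1": "female", "S2": "male", "S3": "female", "S4": "male", "S5": "female", "S6": "male"}

    diet_rows = [diet_row(p, band_favourable[p]) for p in ("S1", "S2", "S3", "S4", "S5", "S6")]
    clin_rows = [clinical_row(p, sexes[p], k) for k, p in enumerate(("S1", "S2", "S3", "S4", "S5", "S6"))]

    # violators: exactly one per exclusion rule
    clin_rows += [
        clinical_row("X_diet", "male", 0),                       # no diet row
        clinical_row("X_energy", "female", 0, energy=400.0),     # implausible energy
        clinical_row("X_diab", "male", 0, diabetes=True),
        clinical_row("X_mets", "female", 0, sbp=np.nan),         # unknown MetS status
        clinical_row("X_micro", "male", 0),                      # no abundance column
        clinical_row("X_abx", "female", 0, antibiotics_6mo=True),
    ]
    diet_rows += [
        diet_row("X_energy", 6, energy_kcal=400.0),
        diet_row("X_diab", 6),
        diet_row("X_mets", 6),
        diet_row("X_micro", 6),
        diet_row("X_abx", 6),
    ]

    diet = pd.DataFrame(diet_rows)
    clinical = pd.DataFrame(clin_rows)

    sample_ids = [p for p in clinical["pid"] if p != "X_micro"]
    base = np.array([300, 250, 150, 100, 80, 60, 40, 20], dtype=np.int64)
    counts = np.column_stack([base + 7 * i for i in range(len(sample_ids))])
    abundance = AbundanceTable([f"MGS{j:02d}" for j in range(1, 9)], sample_ids, counts)

    expected_totals = {p: 4 * band_favourable[p] for p in band_favourable}
    truth = {
        "n_participants": int(len(clinical)),
        "pids": list(clinical["pid"]),
        "expected_totals": expected_totals,
        "expected_bands": {"S1": 1, "S2": 2, "S3": 3, "S4": 4, "S5": 5, "S6": 2},
        "n_met": {p: k for k, p in enumerate(("S1", "S2", "S3", "S4", "S5", "S6"))},
        "violators": {
            "missing_diet": "X_diet",
            "extreme_energy": "X_energy",
            "diabetes": "X_diab",
            "missing_mets": "X_mets",
            "missing_microbiome": "X_micro",
            "antibiotics": "X_abx",
        },
    }
    return SyntheticCohort(diet=diet, clinical=clinical, abundance=abundance, truth=truth)
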