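"""Construction of the Swedish dietary guideline index (SweDGI).

The index aggregates adherence to 12 food-based dietary guidelines.  Each
component is scored 0-4 by how far the participant's intake deviates from
the recommended level, in the favourable or unfavourable direction:

* 4 points - intake meets the recommendation (deviation <= 0);
* 3 points - intake falls short by less than 25 %;
* 2 points - short by 25 % to < 50 %;
* 1 point  - short by 50 % to < 75 %;
* 0 points - short by 75 % or more.

For encouraged foods the deviation is the shortfall below the recommended
level; for restricted foods it is the excess above it, so intake at or below
a maximum scores 4.  Salt is the one composite component: 0-3 points for
energy-standardized salt intake plus 1 point for not salting at the table.
Component points sum to a 0-48 total, binned into five adherence categories.

Added sugar is derived from total sugars by subtracting the sugars naturally
present in fruit and berries (10 %), vegetables (3 %) and juice (8 %).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .guidelines import GuidelineSpec, load_guidelines

__all__ = [
    "KCAL_TO_MJ",
    "PUBLISHED_CUTPOINTS",
    "derive_added_sugar",
    "energy_standardize",
    "score_component",
    "score_salt",
    "compute_swedgi",
    "bin_scores",
]

logger = logging.getLogger(__name__)

#: thermochemical calorie: 1 kcal = 4.1868 kJ
KCAL_TO_MJ = 0.0041868

#: upper edges of total-score categories 1-4 (category 5 is everything above)
PUBLISHED_CUTPOINTS = (18, 22, 25, 29)

_SUGAR_FIELDS = ("sucrose", "fructose", "glucose", "fruits_berries", "vegetables", "juice")
#: naturally occurring sugar fractions subtracted from total sugars
_NATURAL_SUGAR_COEF = {"fruits_berries": 0.10, "vegetables": 0.03, "juice": 0.08}


def derive_added_sugar(record) -> float:
    """Added sugar (g/day) from total sugars minus naturally occurring sugars.

    ``record`` is any mapping (or pandas row) with the fields ``sucrose``,
    ``fructose``, ``glucose``, ``fruits_berries``, ``vegetables`` and
    ``juice`` in g/day.  The subtraction can go below zero for diets rich in
    fruit but poor in sweetened foods; negative grams are clamped to 0.
    """
    vals = {}
    for f in _SUGAR_FIELDS:
        v = float(record[f])
        if v < 0:
            raise ValueError(f"intake {f!r} must be non-negative, got {v}")
        vals[f] = v
    raw = (
        vals["sucrose"]
        + vals["fructose"]
        + vals["glucose"]
        - _NATURAL_SUGAR_COEF["fruits_berries"] * vals["fruits_berries"]
        - _NATURAL_SUGAR_COEF["vegetables"] * vals["vegetables"]
        - _NATURAL_SUGAR_COEF["juice"] * vals["juice"]
    )
    return max(0.0, raw)


def _added_sugar_frame(diet: pd.DataFrame) -> pd.Series:
    raw = (
        diet["sucrose"]
        + diet["fructose"]
        + diet["glucose"]
        - 0.10 * diet["fruits_berries"]
        - 0.03 * diet["vegetables"]
        - 0.08 * diet["juice"]
    )
    return raw.clip(lower=0.0)


def energy_standardize(intake, energy_kcal):
    """Convert a g/day intake to g/MJ of reported energy.

    Scale-invariant: multiplying both intake and energy by a constant leaves
    the result unchanged.
    """
    energy_mj = np.asarray(energy_kcal, dtype=float) * KCAL_TO_MJ
    if np.any(np.asarray(energy_mj) <= 0):
        raise ValueError("energy must be > 0 kcal/day for energy standardization")
    out = np.asarray(intake, dtype=float) / energy_mj
    if np.isscalar(intake) or np.ndim(intake) == 0:
        return float(out)
    return out


def _deviation(intake, spec: GuidelineSpec):
    """Relative deviation from the recommendation in the unfavourable direction."""
    rec = spec.recommended_level
    intake = np.asarray(intake, dtype=float)
    if spec.direction == "encourage":
        return (rec - intake) / rec
    return (intake - rec) / rec


def _points_from_deviation(d):
    """Map relative deviation to 0-4 points (vectorized).

    The deviation brackets are half-open on the left ('< 25 %' strict), so a
    deviation of exactly 25 % scores 2 points.
    """
    d = np.asarray(d, dtype=float)
    return np.select(
        [d <= 0.0, d < 0.25, d < 0.50, d < 0.75],
        [4, 3, 2, 1],
        default=0,
    )


def score_component(intake: float, spec: GuidelineSpec) -> int:
    """Score one proportional 0-4 component for a single intake value.

    ``intake`` must already be on the spec's basis (g/day or g/MJ).
    """
    if spec.scoring != "proportional_5level":
        raise ValueError(
            f"component {spec.name!r} uses scoring {spec.scoring!r}; "
            f"score_component handles 'proportional_5level' only"
        )
    return int(_points_from_deviation(_deviation(intake, spec)))


def score_salt(salt_g_mj: float, salts_at_table: bool, spec: GuidelineSpec) -> int:
    """Score the two-criterion salt component (0-4).

    Criterion 1 compresses the proportional scheme to 0-3 points on
    energy-standardized salt intake; criterion 2 awards 1 point for not
    salting at the table.
    """
    if spec.scoring != "salt_composite":
        raise ValueError(f"component {spec.name!r} is not a salt_composite component")
    if salts_at_table is None or (isinstance(salts_at_table, float) and np.isnan(salts_at_table)):
        raise ValueError("salting-at-table flag is missing; component cannot be scored")
    d = _deviation(salt_g_mj, spec)
    crit1 = int(np.select([np.asarray(d) <= 0.0, np.asarray(d) < 0.25, np.asarray(d) < 0.50], [3, 2, 1], default=0))
    crit2 = 0 if bool(salts_at_table) else 1
    return crit1 + crit2


def _component_intake(diet: pd.DataFrame, spec: GuidelineSpec, variant: str) -> pd.Series:
    """Resolve a component's intake on the basis the variant requires."""
    if spec.derived == "added_sugar":
        base = _added_sugar_frame(diet)
    elif len(spec.source_fields) == 1:
        base = diet[spec.source_fields[0]].astype(float)
    else:
        base = diet[spec.source_fields].astype(float).sum(axis=1, skipna=False)
    per_mj = variant == "per_MJ" or spec.basis == "grams_per_MJ"
    if per_mj:
        return base / (diet["energy"].astype(float) * KCAL_TO_MJ)
    return base


def _recommended_level(spec: GuidelineSpec, variant: str) -> float:
    if variant == "per_MJ" or spec.basis == "grams_per_MJ":
        if spec.recommended_level_per_mj is None:
            raise ValueError(
                f"component {spec.name!r} has no recommended_level_per_mj for the per-MJ variant"
            )
        return spec.recommended_level_per_mj
    return spec.recommended_level


def compute_swedgi(
    diet: pd.DataFrame,
    specs: Sequence[GuidelineSpec] | None = None,
    variant: str = "absolute",
    bin_mode: str = "published_cutpoints",
    k: int = 5,
) -> pd.DataFrame:
    """Score every participant on all 12 components and aggregate.

    Parameters
    ----------
    diet
        Diet table with a ``pid`` column, food/nutrient intakes in g/day,
        ``energy`` in kcal/day and the boolean ``salts_at_table``.
    specs
        Guideline specs; defaults to the shipped 2015 configuration.
    variant
        ``"absolute"`` (g/day, salt per MJ as always), ``"per_MJ"`` (every
        component energy-standardized) or ``"nnr2023"`` (NNR2023-aligned
        reference levels on the absolute basis).
    bin_mode, k
        Passed to :func:`bin_scores` for the adherence category.

    Returns
    -------
    DataFrame with ``pid``, one ``comp_<name>`` column per component,
    ``total`` (0-48) and ``category`` (1-5).  Participants missing any
    required input are dropped (complete-case) with a log entry.
    """
    if variant == "nnr2023":
        specs = load_guidelines("swedgi_nnr2023") if specs is None else specs
        variant = "absolute"
    elif specs is None:
        specs = load_guidelines("swedgi_2015")
    if variant not in ("absolute", "per_MJ"):
        raise ValueError(f"unknown variant {variant!r}")
    if len(specs) != 12:
        raise ValueError(f"expected 12 component specs, got {len(specs)}")

    if "pid" not in diet.columns:
        raise ValueError("diet table must have a 'pid' column")
    needed: set[str] = {"energy"}
    for spec in specs:
        for f in spec.source_fields:
            if f not in diet.columns:
                raise ValueError(
                    f"component {spec.name!r}: source field {f!r} missing from diet table"
                )
        needed.update(spec.source_fields)
        if spec.scoring == "salt_composite":
            if "salts_at_table" not in diet.columns:
                raise ValueError(
                    f"component {spec.name!r}: source field 'salts_at_table' missing from diet table"
                )
            needed.add("salts_at_table")

    complete = diet[sorted(needed)].notna().all(axis=1) & (diet["energy"] > 0)
    if not complete.all():
        dropped = diet.loc[~complete, "pid"].tolist()
        logger.warning(
            "compute_swedgi: dropping %d participant(s) with missing component inputs: %s",
            len(dropped),
            dropped[:10],
        )
    data = diet.loc[complete].reset_index(drop=True)

    out = pd.DataFrame({"pid": data["pid"]})
    for spec in specs:
        intake = _component_intake(data, spec, variant)
        rec = _recommended_level(spec, variant)
        if spec.direction == "encourage":
            d = (rec - intake) / rec
        else:
            d = (intake - rec) / rec
        if spec.scoring == "salt_composite":
            crit1 = np.select([d <= 0.0, d < 0.25, d < 0.50], [3, 2, 1], default=0)
            crit2 = (~data["salts_at_table"].astype(bool)).astype(int)
            pts = crit1 + crit2
        else:
            pts = _points_from_deviation(d)
        out[f"comp_{spec.name}"] = np.asarray(pts, dtype=int)

    comp_cols = [c for c in out.columns if c.startswith("comp_")]
    out["total"] = out[comp_cols].sum(axis=1)
    out["category"] = bin_scores(out["total"], mode=bin_mode, k=k)
    return out


def bin_scores(totals, mode: str = "published_cutpoints", k: int = 5):
    """Bin total scores into adherence categories 1..k.

    ``published_cutpoints`` applies the published five-category cutpoints
    (<=18, 19-22, 23-25, 26-29, >=30).  ``equal_frequency`` emulates
    SPSS-style ntiles: groups as equal as possible, identical totals always
    sharing a group.
    """
    totals = pd.Series(totals).astype(float)
    if totals.empty:
        raise ValueError("totals must be non-empty")
    if mode == "published_cutpoints":
        cats = np.digitize(totals.to_numpy(), [c + 0.5 for c in PUBLISHED_CUTPOINTS]) + 1
        return pd.Series(cats, index=totals.index, name="category")
    if mode != "equal_frequency":
        raise ValueError(f"unknown binning mode {mode!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = totals.nunique()
    if k > n_distinct:
        raise ValueError(
            f"cannot form {k} equal-frequency groups from {n_distinct} distinct total(s)"
        )
    n = len(totals)
    # mean rank per tie group -> ntile; then force monotone over sorted values
    mean_rank = totals.rank(method="average")
    ntile = np.ceil(mean_rank * k / n).astype(int).clip(1, k)
    mapping = (
        pd.DataFrame({"v": totals, "g": ntile})
        .groupby("v")["g"]
        .first()
        .sort_index()
        .cummax()
    )
    return totals.map(mapping).astype(int).rename("category")
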