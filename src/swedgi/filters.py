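"""The exclusion cascade that turns an enrolled cohort into an analysis sample.

Steps mirror standard practice for diet-microbiome epidemiology: drop
participants without dietary data, with implausible reported energy intake
(women < 500 or > 5,000 kcal/day, men < 550 or > 6,000 kcal/day; the
comparisons are strict, so a woman reporting exactly 500 kcal is kept), with
known diabetes at baseline (questionnaire flag only), with unknown MetS
status (any missing criterion input), and - for microbiome analyses - those
without metagenomic data.  A sensitivity step removes participants who used
antibiotics in the 6 months before sampling.

Every step emits an :class:`ExclusionAudit` row, and each participant is
excluded at the first failing step only, so audit counts sum exactly to the
difference between input and output sample sizes.  All rules are
participant-local predicates: reordering the cascade can change per-step
counts but never the final kept set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .mets import classify_cohort

__all__ = [
    "ENERGY_CUTOFFS",
    "ExclusionAudit",
    "energy_plausibility",
    "apply_exclusions",
    "DEFAULT_CASCADE",
    "MICROBIOME_CASCADE",
    "RULES",
]

#: (lower, upper) kcal/day bounds of plausible reported energy, by sex;
#: exclusion is strict (< lower or > upper)
ENERGY_CUTOFFS = {"female": (500.0, 5000.0), "male": (550.0, 6000.0)}


@dataclass(frozen=True)
class ExclusionAudit:
    step: str
    rule: str
    n_before: int
    n_excluded: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - self.n_excluded:
            raise ValueError("audit conservation violated: n_after != n_before - n_excluded")


def energy_plausibility(sex: str, energy: float) -> bool:
    """Keep iff reported energy lies within the sex-specific open interval.

    Missing energy is treated as implausible (exclusion with a distinct
    reason recorded by the cascade).
    """
    if sex not in ENERGY_CUTOFFS:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if energy is None or (isinstance(energy, float) and np.isnan(energy)):
        return False
    lo, hi = ENERGY_CUTOFFS[sex]
    return not (energy < lo or energy > hi)


# -- cascade rules: cohort -> boolean keep-mask aligned with clinical pids --

def _rule_missing_diet(cohort: Cohort) -> pd.Series:
    have_diet = cohort.pids.isin(set(cohort.diet["pid"]))
    return have_diet


def _rule_extreme_energy(cohort: Cohort) -> pd.Series:
    energy = cohort.pids.map(cohort.diet.set_index("pid")["energy"])
    sex = cohort.clinical["sex"]
    lo = sex.map({k: v[0] for k, v in ENERGY_CUTOFFS.items()})
    hi = sex.map({k: v[1] for k, v in ENERGY_CUTOFFS.items()})
    keep = energy.notna() & ~((energy < lo) | (energy > hi))
    return keep


def _rule_diabetes(cohort: Cohort) -> pd.Series:
    diab = cohort.clinical.get("diabetes", pd.Series(False, index=cohort.clinical.index))
    return ~diab.fillna(False).astype(bool)


def _rule_missing_mets(cohort: Cohort) -> pd.Series:
    res = classify_cohort(cohort.clinical)
    return res["classifiable"].reset_index(drop=True)


def _rule_missing_microbiome(cohort: Cohort) -> pd.Series:
    if cohort.abundance is None:
        raise ValueError("missing_microbiome rule requires an abundance table")
    return cohort.pids.isin(set(cohort.abundance.sample_ids))


def _rule_antibiotics(cohort: Cohort) -> pd.Series:
    abx = cohort.clinical.get("antibiotics_6mo", pd.Series(False, index=cohort.clinical.index))
    return ~abx.fillna(False).astype(bool)


RULES: dict[str, tuple[str, callable]] = {
    "missing_diet": ("no dietary data", _rule_missing_diet),
    "extreme_energy": (
        "implausible reported energy (women <500 or >5000, men <550 or >6000 kcal/day; "
        "missing energy excluded)",
        _rule_extreme_energy,
    ),
    "diabetes": ("known diabetes at baseline (questionnaire flag)", _rule_diabetes),
    "missing_mets": ("unknown MetS status (missing criterion input)", _rule_missing_mets),
    "missing_microbiome": ("no metagenomic data", _rule_missing_microbiome),
    "antibiotics": ("antibiotics use in the preceding 6 months", _rule_antibiotics),
}

DEFAULT_CASCADE = ("missing_diet", "extreme_energy", "diabetes", "missing_mets")
MICROBIOME_CASCADE = DEFAULT_CASCADE + ("missing_microbiome",)


def apply_exclusions(
    cohort: Cohort, steps=DEFAULT_CASCADE
) -> tuple[Cohort, list[ExclusionAudit]]:
    """Apply an ordered list of exclusion rules with a full audit trail."""
    for s in steps:
        if s not in RULES:
            raise ValueError(f"unknown exclusion rule {s!r}; known: {sorted(RULES)}")
    current = cohort
    audit: list[ExclusionAudit] = []
    for s in steps:
        rule_text, fn = RULES[s]
        keep = fn(current).to_numpy()
        n_before = current.n
        kept_pids = current.pids[keep]
        current = current.subset(kept_pids)
        audit.append(
            ExclusionAudit(
                step=s,
                rule=rule_text,
                n_before=n_before,
                n_excluded=int((~keep).sum()),
                n_after=current.n,
            )
        )
    return current, audit


def audit_frame(audit: list[ExclusionAudit]) -> pd.DataFrame:
    """Audit trail as a tidy table."""
    return pd.DataFrame([a.__dict__ for a in audit])
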