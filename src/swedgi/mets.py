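"""Rule-based classification of the metabolic syndrome (MetS).

Implements the harmonized IDF/AHA/NHLBI consensus definition: a participant
is classified as having MetS when at least 3 of 5 criteria are met,

* blood pressure: systolic >= 130 mmHg or diastolic >= 85 mmHg,
  or antihypertensive medication;
* fasting glucose >= 5.6 mmol/L;
* triglycerides >= 1.7 mmol/L, or lipid-lowering medication;
* HDL cholesterol <= 1.29 mmol/L (women) / <= 1.03 mmol/L (men),
  or lipid-lowering medication (configurable, see below);
* waist circumference >= 80 cm (women) / >= 94 cm (men).

All comparisons are inclusive at the printed cutpoints.  The consensus
statement counts drug treatment toward hypertension and dyslipidaemia
without splitting the two lipid criteria; by default lipid-lowering
medication therefore satisfies both the triglyceride and the low-HDL
criterion, with ``lipid_med_affects_hdl=False`` restricting it to
triglycerides only.

Participants missing any of the five measured inputs (or sex) are flagged
unclassifiable rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CUTPOINTS", "MetSResult", "evaluate_criteria", "classify_mets", "classify_cohort"]

CUTPOINTS = {
    "sbp": 130.0,
    "dbp": 85.0,
    "fpg": 5.6,
    "tg": 1.7,
    "hdl_female": 1.29,
    "hdl_male": 1.03,
    "waist_female": 80.0,
    "waist_male": 94.0,
}

_REQUIRED = ("sex", "waist", "sbp", "dbp", "fpg", "tg", "hdl")
CRITERIA = ("bp", "glucose", "tg", "hdl", "waist")


@dataclass(frozen=True)
class MetSResult:
    """Criterion flags and classification for one participant."""

    pid: str
    bp: bool
    glucose: bool
    tg: bool
    hdl: bool
    waist: bool

    @property
    def n_met(self) -> int:
        return int(self.bp) + int(self.glucose) + int(self.tg) + int(self.hdl) + int(self.waist)

    @property
    def mets(self) -> bool:
        return classify_mets(self.n_met)


def classify_mets(n_met: int) -> bool:
    """MetS is present when at least 3 of the 5 criteria are met."""
    return n_met >= 3


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def evaluate_criteria(record, lipid_med_affects_hdl: bool = True) -> MetSResult:
    """Evaluate the five MetS criteria for a single participant record.

    ``record`` is a mapping (or pandas row) with the clinical fields.
    Missing medication flags are treated as no reported treatment; missing
    measured inputs raise, mirroring exclusion of participants with unknown
    MetS status.
    """
    missing = [f for f in _REQUIRED if f not in record or _is_missing(record[f])]
    if missing:
        raise ValueError(
            f"participant {record.get('pid', '?')} unclassifiable: missing {missing}"
        )
    sex = record["sex"]
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    aht = bool(record.get("antihypertensive_med")) if not _is_missing(record.get("antihypertensive_med")) else False
    llm = bool(record.get("lipid_lowering_med")) if not _is_missing(record.get("lipid_lowering_med")) else False

    bp = record["sbp"] >= CUTPOINTS["sbp"] or record["dbp"] >= CUTPOINTS["dbp"] or aht
    glucose = record["fpg"] >= CUTPOINTS["fpg"]
    tg = record["tg"] >= CUTPOINTS["tg"] or llm
    hdl_cut = CUTPOINTS["hdl_female"] if sex == "female" else CUTPOINTS["hdl_male"]
    hdl = record["hdl"] <= hdl_cut or (llm and lipid_med_affects_hdl)
    waist_cut = CUTPOINTS["waist_female"] if sex == "female" else CUTPOINTS["waist_male"]
    waist = record["waist"] >= waist_cut
    return MetSResult(
        pid=str(record.get("pid", "?")),
        bp=bool(bp),
        glucose=bool(glucose),
        tg=bool(tg),
        hdl=bool(hdl),
        waist=bool(waist),
    )


def classify_cohort(clinical: pd.DataFrame, lipid_med_affects_hdl: bool = True) -> pd.DataFrame:
    """Vectorized MetS classification for a clinical table.

    Returns a DataFrame with ``pid``, the five criterion flags, ``n_met``,
    ``mets`` and ``classifiable``.  Rows missing any measured input keep
    ``classifiable=False`` and NA flags; callers exclude them (the standard
    handling of unknown MetS status).
    """
    if "pid" not in clinical.columns:
        raise ValueError("clinical table must have a 'pid' column")
    df = clinical
    measured = ["waist", "sbp", "dbp", "fpg", "tg", "hdl"]
    ok = df[measured].notna().all(axis=1) & df["sex"].isin(["female", "male"])

    aht = df.get("antihypertensive_med", pd.Series(False, index=df.index)).fillna(False).astype(bool)
    llm = df.get("lipid_lowering_med", pd.Series(False, index=df.index)).fillna(False).astype(bool)
    female = df["sex"] == "female"

    bp = (df["sbp"] >= CUTPOINTS["sbp"]) | (df["dbp"] >= CUTPOINTS["dbp"]) | aht
    glucose = df["fpg"] >= CUTPOINTS["fpg"]
    tg = (df["tg"] >= CUTPOINTS["tg"]) | llm
    hdl_cut = np.where(female, CUTPOINTS["hdl_female"], CUTPOINTS["hdl_male"])
    hdl = (df["hdl"] <= hdl_cut) | (llm if lipid_med_affects_hdl else False)
    waist_cut = np.where(female, CUTPOINTS["waist_female"], CUTPOINTS["waist_male"])
    waist = df["waist"] >= waist_cut

    out = pd.DataFrame({"pid": df["pid"]})
    flags = pd.DataFrame(
        {"bp": bp, "glucose": glucose, "tg": tg, "hdl": hdl, "waist": waist},
        index=df.index,
    ).astype("boolean")
    flags[~ok] = pd.NA
    out = pd.concat([out, flags], axis=1)
    out["n_met"] = flags.sum(axis=1).where(ok).astype("Int64")
    out["mets"] = (out["n_met"] >= 3).astype("boolean").where(ok)
    out["classifiable"] = ok
    return out
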