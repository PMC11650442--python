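"""Cohort container: the three linked tables of one study sample.

A cohort bundles a diet table (foods and nutrients in g/day, energy in
kcal/day, salting-at-table flag), a clinical table (MetS inputs, covariates
and flags) and an optional species-by-sample count table.  All tables share
the participant identifier column ``pid``; the clinical table is the
enrollment backbone and defines the participant set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .diversity import AbundanceTable

__all__ = ["Cohort", "SyntheticCohort"]


@dataclass
class Cohort:
    diet: pd.DataFrame
    clinical: pd.DataFrame
    abundance: Optional[AbundanceTable] = None

    def __post_init__(self) -> None:
        for name, df in (("diet", self.diet), ("clinical", self.clinical)):
            if "pid" not in df.columns:
                raise ValueError(f"{name} table must have a 'pid' column")

    @property
    def pids(self) -> pd.Series:
        return self.clinical["pid"]

    @property
    def n(self) -> int:
        return len(self.clinical)

    def subset(self, pids) -> "Cohort":
        """Restrict every table to the given participants (order preserved)."""
        pids = list(pids)
        keep = set(pids)
        diet = self.diet[self.diet["pid"].isin(keep)].reset_index(drop=True)
        clinical = self.clinical[self.clinical["pid"].isin(keep)].reset_index(drop=True)
        abundance = self.abundance
        if abundance is not None:
            have = set(abundance.sample_ids)
            present = [p for p in pids if p in have]
            abundance = abundance.select_samples(present)
        return type(self)(**{**self.__dict__, "diet": diet, "clinical": clinical, "abundance": abundance})

    def write(self, outdir: str | Path) -> None:
        """Write the tables as tab-separated text with a one-line header."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.diet.to_csv(outdir / "diet.tsv", sep="\t", index=False)
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        if self.abundance is not None:
            self.abundance.to_tsv(outdir / "abundance.tsv")

    @classmethod
    def read(cls, outdir: str | Path) -> "Cohort":
        outdir = Path(outdir)
        diet = pd.read_csv(outdir / "diet.tsv", sep="\t")
        clinical = pd.read_csv(outdir / "clinical.tsv", sep="\t")
        ab_path = outdir / "abundance.tsv"
        abundance = AbundanceTable.from_tsv(ab_path) if ab_path.exists() else None
        return cls(diet=diet, clinical=clinical, abundance=abundance)


@dataclass
class SyntheticCohort(Cohort):
    """A generated cohort carrying the planted ground truth."""

    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        super().write(outdir)
        (Path(outdir) / "truth.json").write_text(json.dumps(self.truth, indent=2))
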