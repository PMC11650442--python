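"""End-to-end glue: cohort tables in, one analysis-ready table out.

Runs the exclusion cascade, scores the dietary index, classifies MetS,
rarefies the count table and computes Shannon quantile groups, then merges
everything into a single participant-level DataFrame that the association
models consume directly.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohort import Cohort
from .diversity import DEFAULT_DEPTH, downsize_counts, quantile_groups, shannon
from .filters import DEFAULT_CASCADE, MICROBIOME_CASCADE, ExclusionAudit, apply_exclusions
from .index import compute_swedgi
from .mets import classify_cohort

__all__ = ["build_analysis_table"]

_COVARIATE_COLS = [
    "sex", "age", "site", "smoking", "physical_activity", "education",
    "born_in_sweden", "bmi",
]


def build_analysis_table(
    cohort: Cohort,
    specs=None,
    variant: str = "absolute",
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
    n_quantiles: int = 5,
    cascade: Sequence[str] | None = None,
    drop_antibiotics: bool = False,
) -> tuple[pd.DataFrame, list[ExclusionAudit]]:
    """Produce the merged analysis table and the exclusion audit trail.

    Columns of the result: ``pid``, the 12 ``comp_*`` component scores,
    ``swedgi_total``, ``swedgi_category``, ``shannon``, ``shannon_quintile``
    (1..``n_quantiles``), ``mets``/``n_met``, the clinical covariates,
    ``energy`` and ``fibre``.
    """
    if cascade is None:
        cascade = MICROBIOME_CASCADE if cohort.abundance is not None else DEFAULT_CASCADE
    if drop_antibiotics:
        cascade = tuple(cascade) + ("antibiotics",)
    kept, audit = apply_exclusions(cohort, cascade)

    scores = compute_swedgi(kept.diet, specs=specs, variant=variant).rename(
        columns={"total": "swedgi_total", "category": "swedgi_category"}
    )
    mets = classify_cohort(kept.clinical)[["pid", "n_met", "mets", "classifiable"]]

    table = kept.clinical[["pid", *[c for c in _COVARIATE_COLS if c in kept.clinical.columns]]].copy()
    extra = [c for c in ("energy", "fibre") if c in kept.diet.columns]
    table = table.merge(kept.diet[["pid", *extra]], on="pid", how="left")
    table = table.merge(scores, on="pid", how="inner")
    table = table.merge(mets, on="pid", how="left")
    table["mets"] = table["mets"].astype("Int64")

    if kept.abundance is not None and kept.abundance.n_samples > 0:
        rare = downsize_counts(kept.abundance, depth=depth, seed=seed)
        h = shannon(rare).rename("shannon")
        table = table.merge(h.reset_index(), on="pid", how="left")
        with_h = table["shannon"].notna()
        table.loc[with_h, "shannon_quintile"] = quantile_groups(
            table.loc[with_h, "shannon"], n_quantiles
        ).to_numpy()
    return table, audit
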