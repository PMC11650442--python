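"""Rarefied Shannon alpha-diversity from species count tables.

Shotgun-metagenomic samples differ in sequencing depth, and richness-and-
evenness summaries such as the Shannon index grow with depth.  Samples are
therefore first *downsized*: reads are drawn without replacement from each
sample's count column until a fixed depth is reached (a multivariate
hypergeometric draw), and the Shannon index

    H = -sum_i p_i ln p_i   (natural log, nats)

is computed on the downsized counts.  The default depth of 210,430 reads is
the package default for this pipeline; samples shallower than the depth are
dropped rather than scaled, since sampling without replacement is undefined
below depth.

Quantile-group assignment (quintiles for trend models, tertiles for
joint-effect models) is rank based, with tied values always sharing a group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DEPTH",
    "AbundanceTable",
    "downsize_counts",
    "relative_abundance",
    "shannon",
    "quantile_groups",
]

logger = logging.getLogger(__name__)

DEFAULT_DEPTH = 210_430


@dataclass
class AbundanceTable:
    """Species-by-sample matrix of integer read counts."""

    species_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_species, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.species_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.species_ids)} species x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids) -> "AbundanceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return AbundanceTable(list(self.species_ids), list(sample_ids), self.counts[:, idx])

    # -- plain-text round trip (first column species id, header of sample ids)
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.species_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("species_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


def downsize_counts(
    table: AbundanceTable, depth: int = DEFAULT_DEPTH, seed: int = 0
) -> AbundanceTable:
    """Subsample every sample without replacement to a fixed read depth.

    Each retained sample's column is one multivariate hypergeometric draw of
    exactly ``depth`` reads from its observed counts; samples with fewer
    total reads than ``depth`` are dropped with a log entry.  Deterministic
    given ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"depth must be a positive integer, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "downsize_counts: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped[:10],
        )
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    cols = np.empty((table.n_species, len(kept_ids)), dtype=np.int64)
    j = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        col = table.counts[:, i]
        if totals[i] == depth:
            cols[:, j] = col
        else:
            cols[:, j] = rng.multivariate_hypergeometric(col, depth, method="marginals")
        j += 1
    return AbundanceTable(list(table.species_ids), kept_ids, cols)


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample relative abundance in percent (columns sum to 100)."""
    totals = table.sample_totals().astype(float)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    return pd.DataFrame(
        100.0 * table.counts / totals, index=table.species_ids, columns=table.sample_ids
    )


def shannon(table: AbundanceTable) -> pd.Series:
    """Shannon index per sample, natural log, over species with p > 0."""
    totals = table.sample_totals().astype(float)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"empty sample(s): {zero}")
    p = table.counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=0)
    return pd.Series(h, index=pd.Index(table.sample_ids, name="pid"), name="shannon")


def quantile_groups(values, q: int = 5) -> pd.Series:
    """Rank-based assignment into ``q`` groups of near-equal size (1..q).

    Tied values share a group; larger values never receive a smaller group
    index.  Raises when there are fewer observations than groups or when all
    values are identical (no valid split).
    """
    values = pd.Series(values).astype(float)
    if values.isna().any():
        raise ValueError("values must not contain missing entries")
    n = len(values)
    if n < q:
        raise ValueError(f"cannot form {q} groups from {n} observations")
    if values.nunique() < 2:
        raise ValueError("all values identical; quantile groups undefined")
    mean_rank = values.rank(method="average")
    g = np.ceil(mean_rank * q / n).astype(int).clip(1, q)
    mapping = (
        pd.DataFrame({"v": values, "g": g}).groupby("v")["g"].first().sort_index().cummax()
    )
    return values.map(mapping).astype(int).rename("quantile_group")
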