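"""Abundant/rare subcommunity partitioning and diversity profiles.

The rare-biosphere convention used here classifies each taxon by relative
abundance against two thresholds.  *Locally*, classification is per
(taxon, sample) cell with the 0.1% / 0.01% cut-offs; *regionally*, it is
per taxon using the mean relative abundance across all samples with the
0.01% / 0.001% cut-offs.  Boundaries are inclusive on both named classes:
abundant means ra >= upper threshold, rare means 0 < ra <= lower
threshold, so {abundant, intermediate, rare, absent} is an exhaustive,
disjoint labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .tables import OtuTable, ValidationError

LABELS = ("abundant", "intermediate", "rare", "absent")
LEVELS = ("local", "regional")


def relative_abundance(otu: OtuTable) -> pd.DataFrame:
    """Column-normalized fractions; every sample column sums to one."""
    otu.require_positive_totals()
    counts = otu.counts.astype(float)
    return counts.div(counts.sum(axis=0), axis=1)


def _classify(ra: np.ndarray, abundant: float, rare: float) -> np.ndarray:
    return np.select(
        [ra == 0.0, ra >= abundant, ra <= rare],
        ["absent", "abundant", "rare"],
        default="intermediate",
    )


@dataclass
class SubcommunityPartition:
    """Labels per (OTU, sample) at local level, per OTU at regional level."""

    level: str
    labels: pd.DataFrame | pd.Series
    abundant_threshold: float
    rare_threshold: float

    def counts_by_label(self) -> pd.Series:
        if self.level == "local":
            flat = pd.Series(self.labels.to_numpy().ravel())
        else:
            flat = pd.Series(self.labels.to_numpy())
        return flat.value_counts().reindex(LABELS, fill_value=0)


def partition_local(
    rel: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> SubcommunityPartition:
    """Classify every (OTU, sample) cell by its within-sample fraction."""
    cfg = cfg or AnalysisConfig()
    labels = pd.DataFrame(
        _classify(rel.to_numpy(), cfg.local_abundant, cfg.local_rare),
        index=rel.index,
        columns=rel.columns,
    )
    return SubcommunityPartition("local", labels, cfg.local_abundant, cfg.local_rare)


def partition_regional(
    rel: pd.DataFrame, cfg: AnalysisConfig | None = None, otu: OtuTable | None = None
) -> SubcommunityPartition:
    """Classify every OTU by its abundance across all samples.

    ``regional_mode="mean"`` uses the unweighted mean of per-sample
    fractions (robust to unequal library sizes); ``"pooled"`` uses the
    fraction of pooled raw counts and requires ``otu``.
    """
    cfg = cfg or AnalysisConfig()
    if cfg.regional_mode == "mean":
        summary = rel.mean(axis=1)
    else:
        if otu is None:
            raise ValueError("regional_mode='pooled' requires the OtuTable")
        totals = otu.counts.sum(axis=1)
        summary = totals / totals.sum()
    labels = pd.Series(
        _classify(summary.to_numpy(), cfg.regional_abundant, cfg.regional_rare),
        index=rel.index,
    )
    return SubcommunityPartition(
        "regional", labels, cfg.regional_abundant, cfg.regional_rare
    )


def extract_subcommunity(
    otu: OtuTable, part: SubcommunityPartition, which: str
) -> OtuTable:
    """Restrict a count table to one abundance class.

    Local level: cells whose label differs from ``which`` are zeroed
    (membership is sample-specific) and all-zero rows are dropped.
    Regional level: whole OTU rows are kept or dropped.
    """
    if which not in ("abundant", "rare", "intermediate"):
        raise ValueError(f"cannot extract label {which!r}")
    if part.level == "local":
        if not part.labels.index.equals(otu.counts.index) or not part.labels.columns.equals(
            otu.counts.columns
        ):
            raise ValidationError("partition does not match the OTU table")
        mask = (part.labels == which).to_numpy()
        counts = otu.counts.where(mask, 0)
        counts = counts.loc[counts.sum(axis=1) > 0]
    else:
        if not part.labels.index.equals(otu.counts.index):
            raise ValidationError("partition does not match the OTU table")
        counts = otu.counts.loc[part.labels == which]
    if counts.shape[0] == 0:
        warnings.warn(
            f"extraction of {part.level!r} {which!r} subcommunity is empty",
            stacklevel=2,
        )
    taxonomy = otu.taxonomy.reindex(counts.index) if otu.taxonomy is not None else None
    return OtuTable(counts.copy(), taxonomy=taxonomy)


def diversity_profile(matrix: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats) and Gini-Simpson diversity.

    Accepts an OTU table (taxa x samples) or any non-negative DataFrame
    with samples as columns.  All-zero samples yield (0, 0, 0) with a
    warning.
    """
    if isinstance(matrix, OtuTable):
        matrix = matrix.counts
    vals = matrix.to_numpy(dtype=float)
    if vals.size and np.any(vals < 0):
        raise ValidationError("diversity requires a non-negative matrix")
    totals = vals.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        warnings.warn(
            f"all-zero sample(s) {list(matrix.columns[zero])}: diversity set to 0",
            stacklevel=2,
        )
    safe_totals = np.where(zero, 1.0, totals)
    p = vals / safe_totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    richness = (vals > 0).sum(axis=0)
    shannon = -plogp.sum(axis=0)
    simpson = 1.0 - (p**2).sum(axis=0)
    simpson[zero] = 0.0
    shannon[zero] = 0.0
    return pd.DataFrame(
        {
            "richness": richness.astype(int),
            "shannon": shannon,
            "simpson": simpson,
        },
        index=matrix.columns,
    )
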