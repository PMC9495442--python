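"""Core in-memory containers: OTU counts, ecosystem functions, sample design.

Thin, validated wrappers around :class:`pandas.DataFrame` so downstream
stages can rely on orientation (OTU tables are taxa x samples, function
tables are samples x functions) and on exact sample-id matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import VALID_TAGS


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class OtuTable:
    """Integer count matrix, taxa as rows, samples as columns."""

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        vals = c.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if vals.size:
            if np.any(~np.isfinite(vals)):
                raise ValidationError("counts contain non-finite values")
            if np.any(vals < 0):
                r, s = np.argwhere(vals < 0)[0]
                raise ValidationError(
                    f"negative count at OTU {c.index[r]!r}, sample {c.columns[s]!r}"
                )
            if np.any(vals != np.floor(vals)):
                r, s = np.argwhere(vals != np.floor(vals))[0]
                raise ValidationError(
                    f"non-integer count at OTU {c.index[r]!r}, sample {c.columns[s]!r}"
                )
        self.counts = c.astype(np.int64)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(c.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def require_positive_totals(self) -> None:
        totals = self.sample_totals()
        empty = totals.index[totals == 0].tolist()
        if empty:
            raise ValidationError(f"empty sample(s) with zero total counts: {empty}")

    def subset_samples(self, sample_ids) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return OtuTable(self.counts.loc[:, list(sample_ids)].copy(), self.taxonomy)


@dataclass
class FunctionTable:
    """Real-valued samples x functions matrix with element-cycle tags."""

    values: pd.DataFrame
    tags: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate function ids: {dup}")
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if v.isna().any().any():
            bad = [
                (v.index[int(i)], v.columns[int(j)])
                for i, j in np.argwhere(v.isna().to_numpy())
            ]
            raise ValidationError(f"missing values at (sample, function): {bad[:10]}")
        self.values = v.astype(float)
        if self.tags is None:
            from .config import tags_from_groups

            self.tags = pd.Series(tags_from_groups(v.columns))
        self.tags = self.tags.reindex(v.columns)
        if self.tags.isna().any():
            missing = self.tags.index[self.tags.isna()].tolist()
            raise ValidationError(f"no group tag for function(s): {missing}")
        bad_tags = sorted(set(self.tags) - set(VALID_TAGS))
        if bad_tags:
            raise ValidationError(f"invalid function tags: {bad_tags}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def function_ids(self) -> list[str]:
        return list(self.values.columns)

    def ids_with_tag(self, tag: str) -> list[str]:
        return list(self.tags.index[self.tags == tag])


GROUPS_DEFAULT = ("MZ", "IZ", "MS", "IS")
PLANT_OF_GROUP = {"MZ": "Z.mays", "IZ": "Z.mays", "MS": "S.davidii", "IS": "S.davidii"}
SYSTEM_OF_GROUP = {
    "MZ": "sole",
    "IZ": "intercropping",
    "MS": "sole",
    "IS": "intercropping",
}


@dataclass
class SampleDesign:
    """Sample-to-group assignment for the 2 plants x 2 systems layout.

    ``frame`` is indexed by sample id with columns ``group``, ``plant`` and
    ``system``; plant and system jointly determine the group label.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("group", "plant", "system"):
            if col not in f.columns:
                raise ValidationError(f"design table missing column {col!r}")
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in design: {dup}")
        combo = f.groupby(["plant", "system"])["group"].nunique()
        if (combo > 1).any():
            raise ValidationError("plant x system must determine a unique group")
        self.frame = f

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.frame["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def group_labels(self, sample_ids=None) -> pd.Series:
        labels = self.frame["group"]
        if sample_ids is not None:
            labels = labels.reindex(sample_ids)
            if labels.isna().any():
                missing = labels.index[labels.isna()].tolist()
                raise ValidationError(f"samples absent from design: {missing}")
        return labels

    def samples_in_group(self, group: str) -> list[str]:
        out = list(self.frame.index[self.frame["group"] == group])
        if not out:
            raise ValidationError(f"no samples in group {group!r}")
        return out

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in_group(g)) for g in self.groups}

    @classmethod
    def balanced(
        cls, groups=GROUPS_DEFAULT, reps: int = 5, sep: str = "_"
    ) -> "SampleDesign":
        """Build the standard 4-group x ``reps`` replicated design."""
        rows = []
        for g in groups:
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "sample_id": f"{g}{sep}{r}",
                        "group": g,
                        "plant": PLANT_OF_GROUP.get(g, g),
                        "system": SYSTEM_OF_GROUP.get(g, "sole"),
                    }
                )
        frame = pd.DataFrame(rows).set_index("sample_id")
        return cls(frame)


@dataclass
class ValidationReport:
    """Outcome of cross-checking an OTU table, function table and design."""

    ok: bool
    messages: list[str]
    warnings: list[str]
    group_sizes: dict[str, int]
    sparsity: dict[str, float]

    def __str__(self) -> str:
        status = "ok" if self.ok else "MISMATCH"
        lines = [f"dataset validation: {status}"]
        lines += [f"  error: {m}" for m in self.messages]
        lines += [f"  warning: {w}" for w in self.warnings]
        lines.append(f"  group sizes: {self.group_sizes}")
        lines.append(f"  sparsity: {self.sparsity}")
        return "\n".join(lines)


def validate_dataset(
    otu: OtuTable, fn: FunctionTable, design: SampleDesign
) -> ValidationReport:
    """Report sample-id agreement, group sizes and sparsity; never mutates.

    The pipeline refuses to run when ``ok`` is false; warnings (e.g. groups
    with a single replicate) do not block execution.
    """
    messages: list[str] = []
    warns: list[str] = []
    d = set(design.sample_ids)
    o = set(otu.sample_ids)
    f = set(fn.sample_ids)
    for name, ids in (("otu", o), ("function", f)):
        extra = sorted(ids - d)
        missing = sorted(d - ids)
        if extra:
            messages.append(f"{name} table has samples absent from design: {extra}")
        if missing:
            messages.append(f"{name} table is missing design samples: {missing}")
    totals = otu.sample_totals()
    empty = totals.index[totals == 0].tolist()
    if empty:
        messages.append(f"empty sample column(s) in OTU table: {empty}")
    group_sizes = design.group_sizes()
    for g, n in group_sizes.items():
        if n < 2:
            warns.append(f"group {g!r} has {n} replicate(s): tests underpowered")
        elif n < 3:
            warns.append(
                f"group {g!r} has {n} replicates: normality gate will be skipped"
            )
    zero_frac = float((otu.counts.to_numpy() == 0).mean()) if otu.counts.size else 0.0
    sparsity = {
        "otu_zero_fraction": round(zero_frac, 4),
        "n_taxa": float(otu.n_taxa),
        "n_samples": float(len(otu.sample_ids)),
    }
    return ValidationReport(
        ok=not messages,
        messages=messages,
        warnings=warns,
        group_sizes=group_sizes,
        sparsity=sparsity,
    )
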