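"""Core containers for factorial line x diet omics datasets.

The analysis operates on three aligned tables:

* :class:`FeatureMatrix` — continuous normalized abundances, features in rows
  and samples in columns (transcripts and/or metabolites);
* :class:`SampleMeta` — maps each sample to its genetic line, diet,
  replicate block and measurement platform;
* :class:`PhenotypeTable` — gross phenotypes (pupal weight, triglyceride,
  total sugar) per measurement unit.

All three are thin wrappers around :class:`pandas.DataFrame` that enforce the
alignment invariants the downstream stages rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "FeatureMatrix",
    "PhenotypeTable",
    "ValidationIssue",
    "ValidationReport",
    "TRAIT_NAMES",
]

#: Trait columns the study design names explicitly.  Extra trait columns are
#: accepted everywhere, but these three are what the pipeline reports on.
TRAIT_NAMES = ("weight", "triglyceride", "sugar")

META_COLUMNS = ("sample_id", "line_id", "diet_id", "replicate_id", "platform")


@dataclass
class SampleMeta:
    """Sample annotation: genetic line, diet, replicate block, platform."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample metadata missing column(s): {missing}")
        tab = self.table.loc[:, list(META_COLUMNS)].astype(str).reset_index(drop=True)
        dup = tab["sample_id"][tab["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id(s): {sorted(set(dup))}")
        self.table = tab

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def lines(self) -> list[str]:
        return sorted(self.table["line_id"].unique())

    @property
    def diets(self) -> list[str]:
        # preserve first-appearance order: diets are an ordered treatment set
        return list(dict.fromkeys(self.table["diet_id"]))

    @property
    def replicates(self) -> list[str]:
        return sorted(self.table["replicate_id"].unique())

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("sample_id")

    def subset(self, sample_ids: Sequence[str]) -> "SampleMeta":
        keep = self.table[self.table["sample_id"].isin(set(map(str, sample_ids)))]
        return SampleMeta(keep.copy())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class FeatureMatrix:
    """Features x samples abundance matrix with per-feature kind labels.

    ``data`` is indexed by feature id with one column per sample, ordered to
    match the associated :class:`SampleMeta`.  ``kind`` holds
    ``"transcript"`` or ``"metabolite"`` per feature.
    """

    data: pd.DataFrame
    kind: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()]
            raise ValueError(f"duplicate feature_id(s): {sorted(set(dups))}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if self.kind is None:
            self.kind = pd.Series("transcript", index=self.data.index, name="kind")
        else:
            self.kind = self.kind.reindex(self.data.index).fillna("transcript")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def align_to(self, meta: SampleMeta) -> "FeatureMatrix":
        """Reorder columns to follow the metadata row order (hard-erroring
        on any mismatch between the two sample universes)."""
        mat_samples = set(self.sample_ids)
        meta_samples = set(meta.sample_ids)
        only_mat = sorted(mat_samples - meta_samples)
        only_meta = sorted(meta_samples - mat_samples)
        if only_mat or only_meta:
            raise ValueError(
                "sample universe mismatch between matrix and metadata: "
                f"matrix-only={only_mat}, metadata-only={only_meta}"
            )
        return FeatureMatrix(self.data.loc[:, meta.sample_ids], self.kind)


@dataclass
class PhenotypeTable:
    """Gross phenotype values per measurement unit (typically per sample)."""

    table: pd.DataFrame  # indexed by unit_id, one column per trait

    def __post_init__(self) -> None:
        self.table = self.table.astype(float)
        self.table.index = self.table.index.astype(str)
        self.table.index.name = "unit_id"
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()]
            raise ValueError(f"duplicate unit_id(s): {sorted(set(dups))}")

    @property
    def traits(self) -> list[str]:
        return self.table.columns.tolist()

    @property
    def unit_ids(self) -> list[str]:
        return self.table.index.tolist()


@dataclass
class ValidationIssue:
    severity: str  # "info" | "warning" | "error"
    message: str


@dataclass
class ValidationReport:
    """Outcome of dataset validation; never raises, carries severities."""

    issues: list[ValidationIssue] = field(default_factory=list)
    balanced: bool = True
    n_missing_cells: int = 0
    cell_counts: pd.Series | None = None
    constant_features: list[str] = field(default_factory=list)
    stage_preconditions: dict[str, bool] = field(default_factory=dict)

    def add(self, severity: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, message))

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def summary(self) -> str:
        lines = [
            f"design balanced: {self.balanced}; missing cells: {self.n_missing_cells}",
            f"constant features: {len(self.constant_features)}",
        ]
        for name, ok in self.stage_preconditions.items():
            lines.append(f"stage '{name}' preconditions hold: {ok}")
        for issue in self.issues:
            lines.append(f"[{issue.severity}] {issue.message}")
        return "\n".join(lines)


def _asdict(obj) -> dict:
    return dataclasses.asdict(obj)
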