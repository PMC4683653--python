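"""Tab-delimited readers and writers plus dataset validation.

File dialect: UTF-8, tab-delimited, "." decimal separator, empty string for
missing values.  Round trips through these functions preserve finite doubles
bit-exactly (values are serialised with ``repr``-faithful float formatting).
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .datatypes import (
    META_COLUMNS,
    FeatureMatrix,
    PhenotypeTable,
    SampleMeta,
    ValidationReport,
)

log = logging.getLogger("gxd")

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_sample_meta",
    "write_sample_meta",
    "validate_dataset",
]

_FLOAT_FMT = "%.17g"  # shortest round-trippable float formatting


def read_sample_meta(path: str) -> SampleMeta:
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleMeta(tab)


def write_sample_meta(meta: SampleMeta, path: str) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str, meta_path: str) -> tuple[FeatureMatrix, SampleMeta]:
    """Read an abundance matrix TSV together with its sample metadata.

    The matrix has a header row of sample ids and feature ids in the first
    column; an optional ``kind`` column (``transcript``/``metabolite``) is
    recognised.  Columns are re-ordered to follow the metadata row order; any
    sample present on one side only is a hard error naming the offenders.
    Non-numeric cells are reported with their row/column coordinates.
    """
    meta = read_sample_meta(meta_path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    kind = None
    if "kind" in raw.columns:
        kind = raw.pop("kind").astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (raw != "")
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        coords = [
            f"(feature={raw.index[r]!r}, sample={raw.columns[c]!r}, value={raw.iat[r, c]!r})"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValueError(f"non-numeric cell(s) in {path!r}: {', '.join(coords)}")
    # numpy's string->float conversion is correctly rounded (pd.to_numeric is
    # not), so rebuild the values from the raw strings for bit-exact reads
    arr = raw.to_numpy(dtype=object).copy()
    arr[arr == ""] = "nan"
    exact = pd.DataFrame(arr.astype(float), index=raw.index, columns=raw.columns)
    fm = FeatureMatrix(exact, kind)
    fm = fm.align_to(meta)
    log.info("read feature matrix %s: %d features x %d samples", path, *fm.shape)
    return fm, meta


def write_feature_matrix(fm: FeatureMatrix, path: str, kind_column: bool = False) -> None:
    out = fm.data.copy()
    out.index.name = "feature_id"
    if kind_column:
        out.insert(0, "kind", fm.kind)
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_phenotypes(path: str, required: tuple[str, ...] = ("weight", "triglyceride", "sugar")) -> PhenotypeTable:
    """Read a phenotype TSV (unit_id plus trait columns; blanks = missing)."""
    tab = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise ValueError(f"phenotype file {path!r} missing mandatory column(s): {missing}")
    return PhenotypeTable(tab)


def write_phenotypes(ph: PhenotypeTable, path: str) -> None:
    ph.table.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def validate_dataset(
    fm: FeatureMatrix, meta: SampleMeta, ph: PhenotypeTable | None = None
) -> ValidationReport:
    """Report design balance, missing cells, constant features and whether
    downstream stage preconditions hold.  Never raises."""
    rep = ValidationReport()

    # sample alignment
    mat_samples, meta_samples = set(fm.sample_ids), set(meta.sample_ids)
    if mat_samples != meta_samples:
        rep.add(
            "error",
            f"sample universe mismatch: matrix-only={sorted(mat_samples - meta_samples)}, "
            f"metadata-only={sorted(meta_samples - mat_samples)}",
        )

    # design balance over line x diet x replicate cells
    tab = meta.table
    counts = tab.groupby(["line_id", "diet_id", "replicate_id"], sort=True).size()
    full = pd.MultiIndex.from_product(
        [meta.lines, meta.diets, meta.replicates],
        names=["line_id", "diet_id", "replicate_id"],
    )
    counts = counts.reindex(full, fill_value=0)
    rep.cell_counts = counts
    empty = counts[counts == 0]
    rep.n_missing_cells = int(len(empty))
    rep.balanced = bool(counts.nunique() == 1 and rep.n_missing_cells == 0)
    if rep.n_missing_cells:
        cells = [f"{l}/{d}/{r}" for l, d, r in empty.index[:20]]
        rep.add("warning", f"{rep.n_missing_cells} empty line x diet x replicate cell(s): {cells}")
    elif not rep.balanced:
        rep.add("info", "design complete but unbalanced (unequal cell counts)")
    else:
        rep.add("info", "balanced, 0 missing cells")

    # constant / non-finite features
    vals = fm.values()
    if not np.isfinite(vals[~np.isnan(vals)]).all():
        rep.add("error", "non-finite (inf) values present in feature matrix")
    sd = np.nanstd(vals, axis=1)
    const = [fid for fid, s in zip(fm.feature_ids, sd) if s == 0.0]
    rep.constant_features = const
    for fid in const[:20]:
        rep.add("warning", f"constant feature {fid!r} (zero variance)")

    # phenotype alignment
    if ph is not None:
        unknown = sorted(set(ph.unit_ids) - meta_samples)
        if unknown and len(unknown) == len(ph.unit_ids):
            rep.add("info", "phenotype units are not sample ids (pooled units assumed)")
        n_miss = int(ph.table.isna().sum().sum())
        if n_miss:
            rep.add("info", f"{n_miss} missing phenotype value(s)")

    # stage preconditions
    line_diet = tab.groupby(["line_id", "diet_id"]).size()
    ld_full = pd.MultiIndex.from_product([meta.lines, meta.diets])
    line_diet = line_diet.reindex(ld_full, fill_value=0)
    anova_ok = (
        len(meta.lines) >= 2
        and len(meta.diets) >= 2
        and (line_diet > 0).all()
        and len(meta) > len(meta.lines) * len(meta.diets)
    )
    rep.stage_preconditions["anova"] = bool(anova_ok)
    rep.stage_preconditions["cluster"] = bool(
        fm.shape[0] - len(const) >= 4 and len(line_diet) >= 3
    )
    rep.stage_preconditions["correlate"] = bool(ph is not None and len(line_diet) >= 3)
    if not anova_ok:
        rep.add("warning", "two-way ANOVA preconditions not met "
                           "(need >=2 lines, >=2 diets, no empty line x diet cell, df_E > 0)")
    log.info("validate_dataset: %s", "OK" if rep.ok else "errors present")
    return rep
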