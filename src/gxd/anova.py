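"""Per-feature two-way fixed-effects ANOVA with FDR control.

Each feature (transcript or metabolite abundance) is modelled as

    Y_ijm = mu + G_i + D_j + (GxD)_ij + e_ijm

for the m-th sample of genetic line i on diet j.  Genetic line, diet and
their interaction are fixed effects; sums of squares are Type III
(full-versus-reduced model comparisons under sum-to-zero coding), which on a
balanced complete design equals the classical sequential decomposition.
F ratios are taken against the residual mean square, p-values from the F
distribution, and q-values by Benjamini-Hochberg step-up applied per effect
across features.

The model is exposed statsmodels-style: build :class:`GxDAnova` from the
data, call :meth:`~GxDAnova.fit`, and read estimates off the returned
:class:`GxDAnovaResults`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FeatureMatrix, PhenotypeTable, SampleMeta

log = logging.getLogger("gxd")

__all__ = [
    "GxDAnova",
    "GxDAnovaResults",
    "EffectPartition",
    "fit_gxd_anova",
    "bh_fdr",
    "ls_means",
    "classify_significance",
]

EFFECTS = ("G", "D", "GxD")

#: p-values below this are floored before taking -log10, so NLP stays finite.
P_FLOOR = 1e-300


def nlp(p: np.ndarray | float) -> np.ndarray | float:
    """Negative log10 p-value, with underflow floored at 1e-300."""
    return -np.log10(np.maximum(p, P_FLOOR))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j, mapped back to input order (stable
    under ties: equal p share the same q).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _effects_coding(labels: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n x (L-1)."""
    n, L = len(labels), len(levels)
    idx = {lv: k for k, lv in enumerate(levels)}
    codes = np.array([idx[v] for v in labels])
    X = np.zeros((n, L - 1))
    for k in range(L - 1):
        X[codes == k, k] = 1.0
    X[codes == L - 1, :] = -1.0
    return X


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y on the column span of X."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return np.einsum("ij,ij->j", resid, resid)


class GxDAnova:
    """Two-way genotype x diet fixed-effects ANOVA over many features.

    Parameters
    ----------
    fm : FeatureMatrix
        Features x samples abundance matrix.
    meta : SampleMeta
        Sample annotation; must cover the matrix columns.
    """

    def __init__(self, fm: FeatureMatrix, meta: SampleMeta):
        self.fm = fm.align_to(meta)
        self.meta = meta
        tab = meta.indexed().loc[self.fm.sample_ids]
        self.lines = sorted(tab["line_id"].unique())
        self.diets = list(dict.fromkeys(tab["diet_id"]))
        if len(self.lines) < 2 or len(self.diets) < 2:
            raise ValueError("need at least 2 genetic lines and 2 diets")
        cells = tab.groupby(["line_id", "diet_id"]).size()
        if len(cells) < len(self.lines) * len(self.diets):
            got = set(cells.index)
            missing = [
                c for c in itertools.product(self.lines, self.diets) if c not in got
            ]
            raise ValueError(f"empty line x diet cell(s): {missing}")
        self._tab = tab

    def fit(self) -> "GxDAnovaResults":
        tab = self._tab
        Y = self.fm.values().T  # samples x features
        n = Y.shape[0]
        L, J = len(self.lines), len(self.diets)

        XL = _effects_coding(tab["line_id"].to_numpy(), self.lines)
        XD = _effects_coding(tab["diet_id"].to_numpy(), self.diets)
        XI = np.einsum("ni,nj->nij", XL, XD).reshape(n, -1)
        one = np.ones((n, 1))
        X_full = np.hstack([one, XL, XD, XI])

        df_G, df_D, df_I = L - 1, J - 1, (L - 1) * (J - 1)
        df_E = n - (1 + df_G + df_D + df_I)
        if df_E <= 0:
            raise ValueError(
                "saturated model: no residual degrees of freedom "
                "(need some line x diet cell with >= 2 observations)"
            )

        rss_full = _rss(X_full, Y)
        reductions = {
            "G": np.hstack([one, XD, XI]),
            "D": np.hstack([one, XL, XI]),
            "GxD": np.hstack([one, XL, XD]),
        }
        dfs = {"G": df_G, "D": df_D, "GxD": df_I}

        out = pd.DataFrame(index=pd.Index(self.fm.feature_ids, name="feature_id"))
        mse = rss_full / df_E
        ss_total = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
        # constant features: SS_total is numerically zero, every effect is null
        const = ss_total <= 1e-22 * n * (1.0 + Y.mean(axis=0) ** 2)
        rss_full = np.where(const, 0.0, rss_full)
        mse = np.where(const, 0.0, mse)
        for eff, X_red in reductions.items():
            ss = np.maximum(_rss(X_red, Y) - rss_full, 0.0)
            ss = np.where(const, 0.0, ss)
            ms = ss / dfs[eff]
            with np.errstate(divide="ignore", invalid="ignore"):
                F = np.where(mse > 0, ms / np.where(mse > 0, mse, 1.0), np.where(ms > 0, np.inf, 0.0))
            p = stats.f.sf(F, dfs[eff], df_E)
            p = np.clip(p, P_FLOOR, 1.0)
            out[f"SS_{eff}"] = ss
            out[f"df_{eff}"] = dfs[eff]
            out[f"F_{eff}"] = F
            out[f"p_{eff}"] = p
            out[f"NLP_{eff}"] = nlp(p)
        out["SS_E"] = rss_full
        out["df_E"] = df_E
        out["SS_total"] = ss_total
        for eff in EFFECTS:
            out[f"q_{eff}"] = bh_fdr(out[f"p_{eff}"].to_numpy())
        log.info(
            "fit_gxd_anova: %d features, %d samples, %d lines x %d diets (df_E=%d)",
            Y.shape[1], n, L, J, df_E,
        )
        return GxDAnovaResults(table=out, lines=self.lines, diets=self.diets, n_samples=n)


@dataclass
class GxDAnovaResults:
    """Per-feature ANOVA estimates: sums of squares, F, p, NLP and q."""

    table: pd.DataFrame
    lines: list[str] = field(default_factory=list)
    diets: list[str] = field(default_factory=list)
    n_samples: int = 0

    def significant(self, effect: str, q_threshold: float = 0.05) -> list[str]:
        """Feature ids with q <= threshold for the given effect."""
        if effect not in EFFECTS:
            raise ValueError(f"effect must be one of {EFFECTS}")
        mask = self.table[f"q_{effect}"] <= q_threshold
        return self.table.index[mask].tolist()

    def partition(self, q_threshold: float = 0.05) -> "EffectPartition":
        return classify_significance(self, q_threshold)

    def summary(self, n: int = 10) -> str:
        counts = {e: int((self.table[f"q_{e}"] <= 0.05).sum()) for e in EFFECTS}
        head = (
            f"Two-way G x D ANOVA: {len(self.table)} features, "
            f"{len(self.lines)} lines x {len(self.diets)} diets, n={self.n_samples}\n"
            f"significant at FDR 0.05: G={counts['G']}, D={counts['D']}, GxD={counts['GxD']}\n"
        )
        cols = [c for e in EFFECTS for c in (f"F_{e}", f"p_{e}", f"q_{e}")]
        top = self.table.nsmallest(n, "p_GxD")[cols]
        return head + top.to_string(float_format=lambda v: f"{v:.4g}")


def fit_gxd_anova(fm: FeatureMatrix, meta: SampleMeta) -> GxDAnovaResults:
    """Functional wrapper around ``GxDAnova(fm, meta).fit()``."""
    return GxDAnova(fm, meta).fit()


@dataclass
class EffectPartition:
    """Venn-style partition of features over significant effect subsets."""

    counts: dict[str, int]
    q_threshold: float
    n_features: int

    SUBSETS = ("G", "D", "GxD", "G+D", "G+GxD", "D+GxD", "G+D+GxD", "none")

    def total(self) -> int:
        return sum(self.counts.values())


def classify_significance(res: GxDAnovaResults, q_threshold: float) -> EffectPartition:
    """Count features significant for each subset of {G, D, GxD}."""
    sig = {e: res.table[f"q_{e}"] <= q_threshold for e in EFFECTS}
    counts = {k: 0 for k in EffectPartition.SUBSETS}
    for feat in res.table.index:
        present = [e for e in EFFECTS if bool(sig[e].loc[feat])]
        key = "+".join(present) if present else "none"
        counts[key] += 1
    return EffectPartition(counts=counts, q_threshold=q_threshold, n_features=len(res.table))


def ls_means(
    values: FeatureMatrix | PhenotypeTable,
    meta: SampleMeta,
    grouping: str = "line_diet",
) -> pd.DataFrame:
    """Least-squares means per grouping cell.

    For balanced designs these are the arithmetic cell means; for unbalanced
    data they are the means of the observed values within each nonempty cell
    (the saturated two-way model's predicted cell values).  Returns a
    DataFrame indexed by the grouping cells with one column per feature or
    trait; empty cells are dropped with a warning.
    """
    if grouping == "line_diet":
        keys = ["line_id", "diet_id"]
    elif grouping == "line_diet_replicate":
        keys = ["line_id", "diet_id", "replicate_id"]
    else:
        raise ValueError("grouping must be line_diet or line_diet_replicate")

    if isinstance(values, FeatureMatrix):
        wide = values.data.T  # samples x features
    else:
        wide = values.table  # units x traits (units must be sample ids)

    ann = meta.indexed()
    common = wide.index.intersection(ann.index)
    if len(common) < len(wide):
        log.warning("ls_means: %d unit(s) without metadata dropped", len(wide) - len(common))
    wide = wide.loc[common]
    groups = ann.loc[common, keys]
    lsm = wide.groupby([groups[k] for k in keys]).mean()
    lsm.index.names = keys
    n_expected = int(np.prod([ann[k].nunique() for k in keys]))
    if len(lsm) < n_expected:
        log.warning("ls_means: %d empty grouping cell(s) dropped", n_expected - len(lsm))
    return lsm
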