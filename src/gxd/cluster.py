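"""Modularity-based clustering of correlated features ("MMC" stage).

Features that survived a statistical filter (e.g. genotype-by-diet
significance, or strong correlation with a gross phenotype) are clustered
into modules of co-varying features.  Pairwise correlations (by default
Pearson, on line x diet least-squares means) are turned into an adaptively
sharpened weighted graph, w_ij(s) = |r_ij|^s, and the partition maximising
Newman-Girvan modularity Q is found by leading-eigenvector spectral
bisection with greedy single-feature refinement.  The sharpness s is chosen
from a grid to maximise Q; ties go to the smallest s.  Modules are then
re-indexed by descending average within-module |r| ("average degree of
correlation"), so module 1 is always the most coherent.

A logistic transform 1/(1+exp(-(|r|-tau)/sigma)) is available as an
alternative weighting strategy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import nlp  # noqa: F401  (re-exported convenience)

log = logging.getLogger("gxd")

__all__ = [
    "CorrelationMatrix",
    "ModulePartition",
    "ModularityCluster",
    "feature_correlations",
    "filter_by_factor",
    "mmc",
    "order_and_filter_modules",
    "modularity_q",
]


@dataclass
class CorrelationMatrix:
    """Symmetric feature x feature correlation matrix."""

    feature_ids: list[str]
    r: np.ndarray
    method: str = "pearson"
    n_units: np.ndarray | int = 0  # per-pair complete-case counts, or a scalar

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.feature_ids)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape does not match feature ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise ValueError("|r| exceeds 1")
        np.fill_diagonal(self.r, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.feature_ids, columns=self.feature_ids)


def feature_correlations(
    lsm: pd.DataFrame,
    features: list[str] | None = None,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Pairwise feature correlations over grouping units.

    ``lsm`` is a units x features table (typically line x diet LS-means).
    Missing entries are handled pairwise-complete with per-pair n recorded;
    constant features are dropped with a warning.
    """
    cols = lsm.columns.tolist() if features is None else list(features)
    missing = [f for f in cols if f not in lsm.columns]
    if missing:
        raise KeyError(f"features absent from LS-means table: {missing[:10]}")
    X = lsm[cols]
    if len(X) < 3:
        raise ValueError("need at least 3 units to correlate features")
    sd = X.std(ddof=1)
    const = sd.index[(sd == 0) | sd.isna()].tolist()
    if const:
        warnings.warn(f"dropping {len(const)} constant feature(s) from correlation")
        X = X.drop(columns=const)
    r = X.corr(method=method, min_periods=3)
    notna = X.notna().to_numpy().astype(int)
    n_pairs = notna.T @ notna
    return CorrelationMatrix(
        feature_ids=X.columns.tolist(), r=r.to_numpy(), method=method, n_units=n_pairs
    )


def filter_by_factor(features, criterion, threshold: float, rule: str = "p") -> list[str]:
    """Subset features by a significance criterion.

    ``criterion`` maps feature id -> p (rule="p", kept when p < threshold) or
    q (rule="q", kept when q <= threshold, the ANOVA/FDR convention).
    """
    crit = pd.Series(criterion)
    missing = [f for f in features if f not in crit.index]
    if missing:
        raise KeyError(f"criterion does not cover feature(s): {missing[:10]}")
    if rule == "p":
        kept = [f for f in features if crit[f] < threshold]
    elif rule == "q":
        kept = [f for f in features if crit[f] <= threshold]
    else:
        raise ValueError("rule must be 'p' or 'q'")
    log.info("filter_by_factor: %d of %d features pass %s-threshold %g",
             len(kept), len(list(features)), rule, threshold)
    if not kept:
        warnings.warn("significance filter left no features; clustering should be skipped")
    return kept


def modularity_q(W: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan modularity of a partition of a weighted graph.

    Q = sum over modules of (w_in / W_tot) - (k_mod / W_tot)^2, with
    W_tot = total weight (both orientations) and w_in counting both
    orientations of within-module edges.
    """
    k = W.sum(axis=0)
    tot = k.sum()
    if tot <= 0:
        return 0.0
    q = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        w_in = W[np.ix_(idx, idx)].sum()
        q += w_in / tot - (k[idx].sum() / tot) ** 2
    return float(q)


def _leading_eigvec(Bg: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(Bg)
    v = vecs[:, -1]
    # deterministic sign: the largest-magnitude component is made positive
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v


def _refine_split(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Greedy single-feature moves until no flip increases the split's dQ."""
    s = s.copy()
    Bs = Bg @ s
    for _ in range(100 * len(s)):
        # gain of flipping i: -4 s_i (Bs_i - B_ii s_i)
        gains = -4.0 * s * (Bs - np.diag(Bg) * s)
        i = int(np.argmax(gains))
        if gains[i] <= 1e-13:
            break
        s[i] = -s[i]
        Bs += 2.0 * s[i] * Bg[:, i]
    return s


def _spectral_partition(W: np.ndarray, refine: bool = True) -> np.ndarray:
    """Recursive leading-eigenvector bisection maximising modularity."""
    n = W.shape[0]
    k = W.sum(axis=0)
    tot = k.sum()
    labels = np.zeros(n, dtype=int)
    if tot <= 0:
        return labels
    B = W - np.outer(k, k) / tot
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        g = stack.pop()
        if len(g) < 2:
            continue
        Bg = B[np.ix_(g, g)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        v = _leading_eigvec(Bg)
        s = np.where(v >= 0, 1.0, -1.0)
        if refine:
            s = _refine_split(Bg, s)
        dq = s @ Bg @ s / (2.0 * tot)
        if dq <= 1e-13 or np.all(s == s[0]):
            continue  # indivisible: keep g as a final module
        left, right = g[s > 0], g[s < 0]
        labels[right] = next_label
        next_label += 1
        stack.append(left)
        stack.append(right)
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    return labels


@dataclass
class ModulePartition:
    """Result of modularity clustering: ordered module assignment.

    ``assignment`` maps feature id -> 1-based module index; module 1 has the
    maximal average within-module |r|.  ``module_stats`` carries size and
    avg_abs_corr per module (index = module), with ``excluded`` flags set by
    :func:`order_and_filter_modules`; original (pre-filter) indices are kept
    in its ``original_index`` column.
    """

    assignment: pd.Series
    chosen_sharpness: float
    modularity_Q: float
    module_stats: pd.DataFrame
    transform: str = "power"
    corr: CorrelationMatrix | None = None

    @property
    def n_modules(self) -> int:
        return int((~self.module_stats["excluded"]).sum())

    def members(self, module: int) -> list[str]:
        return self.assignment.index[self.assignment == module].tolist()

    def retained_modules(self) -> list[int]:
        st = self.module_stats
        return st.index[~st["excluded"]].tolist()

    def labels(self) -> np.ndarray:
        return self.assignment.to_numpy()

    def summary(self) -> str:
        head = (
            f"Modularity clustering: {len(self.assignment)} features, "
            f"{self.module_stats.shape[0]} modules "
            f"(Q={self.modularity_Q:.4f}, s={self.chosen_sharpness:g}, "
            f"transform={self.transform})\n"
        )
        return head + self.module_stats.to_string(float_format=lambda v: f"{v:.3f}")

    def plot_heatmap(self, ax=None):
        """Diagnostic heatmap of |r| with features ordered by module."""
        import matplotlib.pyplot as plt  # deferred: plotting is optional

        if self.corr is None:
            raise ValueError("partition carries no correlation matrix")
        order = np.argsort(self.assignment.to_numpy(), kind="stable")
        R = self.corr.r[np.ix_(order, order)]
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(R, cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title("module-ordered correlation heatmap")
        plt.colorbar(im, ax=ax)
        return ax


def _avg_abs_corr(r: np.ndarray, idx: np.ndarray) -> float:
    """Mean |r_ij| over within-module pairs; NaN for singletons."""
    if len(idx) < 2:
        return float("nan")
    sub = np.abs(r[np.ix_(idx, idx)])
    k = len(idx)
    return float((sub.sum() - k) / (k * (k - 1)))


class ModularityCluster:
    """Adaptive-sharpening modularity clustering model.

    Parameters
    ----------
    cm : CorrelationMatrix
        Feature correlations (>= 4 features).
    sharpness_grid : sequence of float
        Candidate sharpening exponents (default 1..30).
    transform : "power" or "logistic"
        Edge weight family: |r|^s, or 1/(1+exp(-(|r|-tau)/s)) with
        tau = ``logistic_tau``.
    refine : bool
        Greedy single-feature refinement of every bisection.
    """

    def __init__(
        self,
        cm: CorrelationMatrix,
        sharpness_grid=None,
        transform: str = "power",
        refine: bool = True,
        logistic_tau: float = 0.5,
    ):
        if len(cm.feature_ids) < 4:
            raise ValueError("clustering needs at least 4 features")
        if transform not in ("power", "logistic"):
            raise ValueError("transform must be 'power' or 'logistic'")
        self.cm = cm
        self.grid = [float(s) for s in (sharpness_grid or range(1, 31))]
        self.transform = transform
        self.refine = refine
        self.logistic_tau = float(logistic_tau)

    def _weights(self, s: float) -> np.ndarray:
        A = np.abs(np.nan_to_num(self.cm.r, nan=0.0))
        if self.transform == "power":
            W = A**s
        else:
            W = 1.0 / (1.0 + np.exp(-(A - self.logistic_tau) / s))
        np.fill_diagonal(W, 0.0)
        return W

    def fit(self) -> ModulePartition:
        best: tuple[float, float, np.ndarray] | None = None  # (Q, s, labels)
        for s in self.grid:
            W = self._weights(s)
            if W.sum() <= 0:
                continue
            labels = _spectral_partition(W, refine=self.refine)
            q = modularity_q(W, labels)
            if best is None or q > best[0] + 1e-12:  # ties keep the smallest s
                best = (q, s, labels)
        ids = self.cm.feature_ids
        if best is None:
            warnings.warn("all edge weights are zero; returning a single module")
            labels = np.zeros(len(ids), dtype=int)
            q, s = 0.0, self.grid[0]
        else:
            q, s, labels = best

        # re-index modules by descending average |r|
        uniq = np.unique(labels)
        stats_rows = []
        for lab in uniq:
            idx = np.flatnonzero(labels == lab)
            stats_rows.append((lab, len(idx), _avg_abs_corr(self.cm.r, idx)))
        stats = pd.DataFrame(stats_rows, columns=["raw_label", "size", "avg_abs_corr"])
        stats = stats.sort_values(
            ["avg_abs_corr", "size"], ascending=[False, False], na_position="last"
        ).reset_index(drop=True)
        stats.index = pd.RangeIndex(1, len(stats) + 1, name="module")
        relabel = {row.raw_label: mod for mod, row in stats.iterrows()}
        assignment = pd.Series(
            [relabel[lab] for lab in labels], index=pd.Index(ids, name="feature_id"),
            name="module",
        )
        stats = stats.drop(columns="raw_label")
        stats["original_index"] = stats.index
        stats["excluded"] = False
        log.info(
            "mmc: %d features -> %d modules, Q=%.4f at s=%g",
            len(ids), len(stats), q, s,
        )
        return ModulePartition(
            assignment=assignment,
            chosen_sharpness=s,
            modularity_Q=q,
            module_stats=stats,
            transform=self.transform,
            corr=self.cm,
        )


def mmc(cm: CorrelationMatrix, sharpness_grid=None, refine: bool = True, **kw) -> ModulePartition:
    """Functional wrapper around ``ModularityCluster(...).fit()``."""
    return ModularityCluster(cm, sharpness_grid=sharpness_grid, refine=refine, **kw).fit()


def order_and_filter_modules(
    part: ModulePartition, min_size: int = 3, min_avg_corr: float = 0.5
) -> ModulePartition:
    """Flag modules failing size or coherence thresholds as excluded.

    Retained modules keep their ordering (module 1 = most coherent); the
    original indices of all modules remain in ``module_stats``.
    """
    stats = part.module_stats.copy()
    avg = stats["avg_abs_corr"].fillna(-np.inf)
    stats["excluded"] = (stats["size"] < min_size) | (avg < min_avg_corr)
    if stats["excluded"].all():
        warnings.warn("all modules fall below the size/coherence thresholds")
    log.info(
        "order_and_filter_modules: retained %d of %d modules "
        "(min_size=%d, min_avg_corr=%g)",
        int((~stats["excluded"]).sum()), len(stats), min_size, min_avg_corr,
    )
    return ModulePartition(
        assignment=part.assignment,
        chosen_sharpness=part.chosen_sharpness,
        modularity_Q=part.modularity_Q,
        module_stats=stats,
        transform=part.transform,
        corr=part.corr,
    )
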