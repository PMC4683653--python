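"""Feature-trait correlation profiles, overlap accounting and stepwise fits.

The correlation unit is the line x diet least-squares mean (n = lines x
diets when pooled, n = lines within one diet).  Per-feature Pearson (or
Spearman) correlations with each gross phenotype give a
:class:`CorrelationProfile` per (trait, diet) scope; profiles feed the
multi-trait/multi-diet Venn overlap counts, and — restricted to features
significantly correlated with a trait — the forward stepwise regression
that finds a minimal explanatory feature set under BIC.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import nlp
from .datatypes import PhenotypeTable

log = logging.getLogger("gxd")

__all__ = [
    "CorrelationProfile",
    "VennCounts",
    "StepwiseResults",
    "ForwardStepwiseBIC",
    "trait_correlations",
    "gross_trait_correlations",
    "venn_overlap",
    "forward_stepwise_bic",
]


@dataclass
class CorrelationProfile:
    """Per-feature correlations with one trait under one scope.

    ``table`` is indexed by feature id with columns r, p, NLP, n.  The r
    column is the vector whose second-order correlation across scopes is the
    conservation statistic.
    """

    trait: str
    diet: str = "pooled"
    platform: str = ""
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def label(self) -> str:
        parts = [self.trait, self.diet]
        if self.platform:
            parts.append(self.platform)
        return ":".join(parts)

    @property
    def r(self) -> pd.Series:
        return self.table["r"]

    def significant(self, p_threshold: float) -> set[str]:
        mask = self.table["p"] < p_threshold
        return set(self.table.index[mask])


def _corr_columns_with(
    X: pd.DataFrame, y: pd.Series, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate every column of X with y on complete cases (vectorized)."""
    mask = y.notna()
    Xv = X.loc[mask]
    yv = y.loc[mask]
    if method == "spearman":
        Xv = Xv.rank()
        yv = yv.rank()
    n_vec = Xv.notna().sum(axis=0).to_numpy()
    Xc = Xv - Xv.mean()
    yc = yv - yv.mean()
    # pairwise-complete: recenter y per column only matters with feature NaNs
    num = Xc.mul(yc, axis=0).sum(skipna=True)
    den = np.sqrt((Xc**2).sum(skipna=True) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (num / den).to_numpy()
    r = np.clip(r, -1.0, 1.0)
    n = n_vec.astype(float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(df > 0, np.clip(p, 1e-300, 1.0), np.nan)
    flagged = (Xv.std(ddof=1) == 0).to_numpy()
    r = np.where(flagged, np.nan, r)
    p = np.where(flagged, np.nan, p)
    out = pd.DataFrame(
        {"r": r, "p": p, "NLP": np.where(np.isnan(p), np.nan, nlp(np.nan_to_num(p, nan=1.0))),
         "n": n_vec},
        index=X.columns,
    )
    return out


def trait_correlations(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    scope: str = "pooled",
    method: str = "pearson",
    platform: str = "",
) -> dict[str, CorrelationProfile]:
    """Per-feature trait correlations over matched units.

    ``features`` and ``traits`` are units x columns LS-means tables sharing
    an index.  ``scope`` is "pooled" or a diet id (restricting to that
    diet's units, which requires a (line_id, diet_id) MultiIndex).  Returns
    one profile per trait column.
    """
    common = features.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 common units between features and traits")
    F = features.loc[common]
    T = traits.loc[common]
    diet = "pooled"
    if scope != "pooled":
        diets = F.index.get_level_values("diet_id")
        sel = diets == scope
        if sel.sum() < 3:
            raise ValueError(f"fewer than 3 units on diet {scope!r}")
        F, T = F.loc[sel], T.loc[sel]
        diet = str(scope)
    profiles: dict[str, CorrelationProfile] = {}
    for trait in T.columns:
        tab = _corr_columns_with(F, T[trait], method=method)
        profiles[trait] = CorrelationProfile(
            trait=trait, diet=diet, platform=platform, table=tab
        )
    log.info("trait_correlations(%s): %d features x %d traits on %d units",
             diet, F.shape[1], T.shape[1], len(F))
    return profiles


def gross_trait_correlations(ph: PhenotypeTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete correlations among raw unit-level traits.

    One row per trait pair with r, count and NLP (the raw-phenotype half of
    the trait co-correlation comparison).
    """
    tab = ph.table if isinstance(ph, PhenotypeTable) else ph
    rows = []
    for a, b in itertools.combinations(tab.columns, 2):
        pair = tab[[a, b]].dropna()
        n = len(pair)
        if n < 3:
            rows.append(dict(trait_1=a, trait_2=b, r=np.nan, n=n, p=np.nan, NLP=np.nan))
            continue
        r, p = stats.pearsonr(pair[a], pair[b])
        rows.append(dict(trait_1=a, trait_2=b, r=float(r), n=n, p=float(p),
                         NLP=float(nlp(max(p, 0.0)))))
    return pd.DataFrame(rows)


@dataclass
class VennCounts:
    """Counts of features significant in exactly each subset of conditions."""

    labels: list[str]
    subset_counts: dict[frozenset, int]
    threshold: float

    def exactly(self, k: int) -> int:
        return sum(c for s, c in self.subset_counts.items() if len(s) == k)

    def total(self) -> int:
        return sum(self.subset_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"conditions": "+".join(sorted(s)), "k": len(s), "count": c}
            for s, c in sorted(self.subset_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows)


def venn_overlap(profiles: list[CorrelationProfile], p_threshold: float) -> VennCounts:
    """Exact per-subset counts of significant features across conditions."""
    universes = [frozenset(p.table.index) for p in profiles]
    if len(set(universes)) > 1:
        raise ValueError("profiles do not share a feature universe")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("profile labels are not unique")
    sig = {lab: p.significant(p_threshold) for lab, p in zip(labels, profiles)}
    counts: dict[frozenset, int] = {}
    union = set().union(*sig.values())
    for feat in union:
        key = frozenset(lab for lab in labels if feat in sig[lab])
        counts[key] = counts.get(key, 0) + 1
    return VennCounts(labels=labels, subset_counts=counts, threshold=p_threshold)


@dataclass
class StepwiseResults:
    """Forward stepwise regression outcome for one trait.

    ``selected`` lists features in entry order; ``bic_trace`` starts at the
    intercept-only model and strictly decreases along accepted steps.
    """

    trait: str
    selected: list[str]
    coefficients: pd.Series
    intercept: float
    r_squared: float
    bic_trace: list[float]
    n: int
    candidate_definition: str = ""

    def summary(self) -> str:
        lines = [
            f"Forward stepwise (BIC) for {self.trait!r}: "
            f"{len(self.selected)} feature(s) selected of candidates "
            f"[{self.candidate_definition}], n={self.n}",
            f"R-squared = {self.r_squared:.4f}",
        ]
        for step, feat in enumerate(self.selected, start=1):
            lines.append(
                f"  step {step}: + {feat}  (BIC {self.bic_trace[step]:.2f}, "
                f"coef {self.coefficients[feat]:+.4f})"
            )
        if not self.selected:
            lines.append("  no candidate lowered BIC; intercept-only model kept")
        return "\n".join(lines)


class ForwardStepwiseBIC:
    """Forward stepwise OLS with BIC = n*ln(RSS/n) + k*ln(n).

    ``k`` counts slope terms plus the intercept.  At each step the candidate
    minimising BIC is added; selection stops when no addition lowers BIC
    strictly.  Ties break toward lexicographically smaller feature ids.
    Candidates collinear with the selected set (R^2 >= 1 - 1e-10) are
    skipped with a warning.

    Per the pipeline's contract the candidate set should already be
    restricted to features significantly correlated with the trait; pass
    ``prefilter_p`` to apply that restriction here (marginal correlation
    p < prefilter_p).
    """

    def __init__(
        self,
        y: pd.Series,
        candidates: pd.DataFrame,
        trait: str | None = None,
        prefilter_p: float | None = None,
    ):
        data = candidates.join(y.rename("__y__"), how="inner").dropna()
        if len(data) < 4:
            raise ValueError("need at least 4 complete units")
        self.y = data["__y__"]
        self.X = data.drop(columns="__y__")
        self.trait = trait or (y.name if y.name is not None else "trait")
        self.candidate_definition = f"{self.X.shape[1]} candidates"
        if prefilter_p is not None:
            prof = _corr_columns_with(self.X, self.y)
            keep = prof.index[prof["p"] < prefilter_p].tolist()
            self.X = self.X[keep]
            self.candidate_definition += f", marginal p < {prefilter_p:g}"
        self.n = len(self.y)

    @staticmethod
    def _bic(n: int, rss: float, k: int) -> float:
        return n * np.log(max(rss, 1e-300) / n) + k * np.log(n)

    def fit(self) -> StepwiseResults:
        y = self.y.to_numpy()
        n = self.n
        tss = float(np.sum((y - y.mean()) ** 2))
        selected: list[str] = []
        bic_trace = [self._bic(n, tss, 1)]
        order = sorted(self.X.columns)
        coef = np.array([y.mean()])
        rss_current = tss
        while True:
            best: tuple[float, str, float, np.ndarray] | None = None
            Xsel = self.X[selected].to_numpy()
            base = np.column_stack([np.ones(n), Xsel])
            for feat in order:
                if feat in selected:
                    continue
                x = self.X[feat].to_numpy()
                # collinearity guard: R^2 of the candidate on selected + 1
                cand_rss = float(np.sum((x - base @ np.linalg.lstsq(base, x, rcond=None)[0]) ** 2))
                cand_tss = float(np.sum((x - x.mean()) ** 2))
                if cand_tss <= 0 or cand_rss <= 1e-10 * cand_tss:
                    warnings.warn(f"skipping collinear candidate {feat!r}")
                    continue
                Xtry = np.column_stack([base, x])
                beta = np.linalg.lstsq(Xtry, y, rcond=None)[0]
                rss = float(np.sum((y - Xtry @ beta) ** 2))
                b = self._bic(n, rss, len(selected) + 2)
                if best is None or b < best[0]:
                    best = (b, feat, rss, beta)
            if best is None or best[0] >= bic_trace[-1]:
                break
            bic_trace.append(best[0])
            selected.append(best[1])
            rss_current = best[2]
            coef = best[3]
        r2 = 1.0 - rss_current / tss if tss > 0 else 0.0
        coefficients = pd.Series(coef[1:], index=selected, name="coefficient")
        log.info("forward_stepwise_bic(%s): selected %d feature(s), R^2=%.4f",
                 self.trait, len(selected), r2)
        return StepwiseResults(
            trait=str(self.trait),
            selected=selected,
            coefficients=coefficients,
            intercept=float(coef[0]),
            r_squared=float(r2),
            bic_trace=bic_trace,
            n=n,
            candidate_definition=self.candidate_definition,
        )


def forward_stepwise_bic(
    candidates: pd.DataFrame,
    trait_values: pd.Series,
    trait: str | None = None,
    prefilter_p: float | None = None,
) -> StepwiseResults:
    """Functional wrapper around ``ForwardStepwiseBIC(...).fit()``."""
    return ForwardStepwiseBIC(
        trait_values, candidates, trait=trait, prefilter_p=prefilter_p
    ).fit()
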