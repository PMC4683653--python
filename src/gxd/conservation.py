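"""Second-order ("co-") correlation of trait-correlation profiles.

The conservation statistic between two conditions (a trait/diet/platform
scope each) is the Pearson correlation between their per-feature
trait-correlation vectors over the common features.  High co-correlation
means the features that track the trait in one condition track it the same
way in the other; its collapse on a novel diet is the signature of cryptic
variation.  A permutation test for multi-condition sharing of significant
feature sets provides the "no more overlap than chance" null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import ls_means
from .correlates import CorrelationProfile, trait_correlations
from .datatypes import FeatureMatrix, PhenotypeTable, SampleMeta
from ._rng import stage_rng

log = logging.getLogger("gxd")

__all__ = [
    "ConservationMatrix",
    "OverlapTest",
    "co_correlation",
    "conservation_matrix",
    "chance_overlap_test",
    "cross_platform",
]

#: NLP values are reported capped here when p underflows double precision;
#: the underlying p is stored as 0 with an underflow flag.
NLP_CAP = 312.0


def _nlp_capped(p: float) -> float:
    if p <= 0.0 or p < 1e-312:
        return NLP_CAP
    return float(-np.log10(p))


def co_correlation(a: CorrelationProfile, b: CorrelationProfile) -> tuple[float, float, int]:
    """Pearson correlation of two r-vectors over their common features.

    Returns (r, p, n) with p from the t-distribution on n-2 df, n = number
    of common features.  The analytic p treats features as independent; see
    :func:`unit_resampling_p` for a resampling alternative.
    """
    common = a.table.index.intersection(b.table.index)
    ra = a.table.loc[common, "r"]
    rb = b.table.loc[common, "r"]
    mask = ra.notna() & rb.notna()
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"fewer than 3 common features between {a.label} and {b.label}")
    r, p = stats.pearsonr(ra[mask], rb[mask])
    return float(r), float(p), n


@dataclass
class ConservationMatrix:
    """All pairwise co-correlations among a list of profile conditions."""

    labels: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n_features: pd.DataFrame
    restriction: str = ""

    @property
    def nlp(self) -> pd.DataFrame:
        return self.p.map(lambda v: np.nan if pd.isna(v) else _nlp_capped(v))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1:]:
                rows.append(
                    dict(condition_1=a, condition_2=b, r=self.r.loc[a, b],
                         p=self.p.loc[a, b], NLP=self.nlp.loc[a, b],
                         n_features=self.n_features.loc[a, b])
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = f"Conservation (co-correlation) matrix over {len(self.labels)} conditions"
        if self.restriction:
            head += f" [{self.restriction}]"
        return head + "\n" + self.r.to_string(float_format=lambda v: f"{v:.4f}")


def conservation_matrix(
    profiles: list[CorrelationProfile], restriction: str = ""
) -> ConservationMatrix:
    """Pairwise co-correlation of all profiles (diagonal = 1 by definition)."""
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("profile labels are not unique")
    k = len(labels)
    R = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    P = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    N = pd.DataFrame(0, index=labels, columns=labels)
    for i in range(k):
        N.iloc[i, i] = len(profiles[i].table)
        for j in range(i + 1, k):
            try:
                r, p, n = co_correlation(profiles[i], profiles[j])
            except ValueError:
                r, p, n = np.nan, np.nan, 0
            R.iloc[i, j] = R.iloc[j, i] = r
            P.iloc[i, j] = P.iloc[j, i] = p
            N.iloc[i, j] = N.iloc[j, i] = n
    return ConservationMatrix(labels=labels, r=R, p=P, n_features=N, restriction=restriction)


@dataclass
class OverlapTest:
    """Permutation test for excess sharing of significant feature sets."""

    observed: dict[int, int]         # multiplicity k -> count of features in exactly k sets
    null_mean: dict[int, float]
    null_sd: dict[int, float]
    p_excess: float                  # one-sided: more sharing (k >= 2) than chance
    null_pairwise_mean: pd.DataFrame  # expected pairwise overlap per set pair
    n_perm: int

    def summary(self) -> str:
        lines = [f"Sharing of significant sets vs {self.n_perm} permutations "
                 f"(p_excess = {self.p_excess:.4g})"]
        for k in sorted(self.observed):
            lines.append(
                f"  in exactly {k} set(s): observed {self.observed[k]}, "
                f"null {self.null_mean.get(k, 0.0):.2f} +/- {self.null_sd.get(k, 0.0):.2f}"
            )
        return "\n".join(lines)


def _multiplicity_counts(sets: list[set], max_k: int) -> np.ndarray:
    counter: dict = {}
    for s in sets:
        for f in s:
            counter[f] = counter.get(f, 0) + 1
    out = np.zeros(max_k + 1, dtype=int)
    for v in counter.values():
        out[v] += 1
    return out


def chance_overlap_test(
    sig_sets: list[set],
    universe_size: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapTest:
    """Null: independent uniform same-size draws from the feature universe.

    The excess-sharing statistic is the number of features significant in
    two or more conditions; its one-sided permutation p is
    (1 + #{perm >= observed}) / (n_perm + 1).
    """
    sizes = [len(s) for s in sig_sets]
    if any(sz > universe_size for sz in sizes):
        raise ValueError("a significant set exceeds the universe size")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    K = len(sig_sets)
    observed = _multiplicity_counts([set(s) for s in sig_sets], K)
    obs_shared = int(observed[2:].sum())

    rng = stage_rng(seed, "chance_overlap")
    null_counts = np.zeros((n_perm, K + 1), dtype=int)
    null_pair = np.zeros((K, K))
    exceed = 0
    for b in range(n_perm):
        draws = [set(rng.choice(universe_size, size=sz, replace=False).tolist()) for sz in sizes]
        cnt = _multiplicity_counts(draws, K)
        null_counts[b] = cnt
        if int(cnt[2:].sum()) >= obs_shared:
            exceed += 1
        for i in range(K):
            for j in range(i + 1, K):
                null_pair[i, j] += len(draws[i] & draws[j])
    null_pair = (null_pair + null_pair.T) / n_perm
    p_excess = (1 + exceed) / (n_perm + 1)
    return OverlapTest(
        observed={k: int(observed[k]) for k in range(1, K + 1)},
        null_mean={k: float(null_counts[:, k].mean()) for k in range(1, K + 1)},
        null_sd={k: float(null_counts[:, k].std(ddof=1)) for k in range(1, K + 1)},
        p_excess=float(p_excess),
        null_pairwise_mean=pd.DataFrame(null_pair),
        n_perm=n_perm,
    )


def cross_platform(
    a: tuple[FeatureMatrix, SampleMeta, PhenotypeTable],
    b: tuple[FeatureMatrix, SampleMeta, PhenotypeTable],
    trait: str,
    common_lines_only: bool = False,
    method: str = "pearson",
) -> ConservationMatrix:
    """Conservation of one trait's correlation profiles across platforms/diets.

    For each dataset (platform) and each of its diets, features and the
    trait are collapsed to per-line LS-means within the diet and correlated
    across lines over the shared features (optionally restricted to the
    shared genetic lines); the full co-correlation matrix over all
    (platform, diet) conditions is returned.
    """
    (fm_a, meta_a, ph_a), (fm_b, meta_b, ph_b) = a, b
    feats = sorted(set(fm_a.feature_ids) & set(fm_b.feature_ids))
    if len(feats) < 3:
        raise ValueError("fewer than 3 common features between platforms")
    restriction = ""
    lines_keep = None
    if common_lines_only:
        lines_keep = sorted(set(meta_a.lines) & set(meta_b.lines))
        if len(lines_keep) < 3:
            raise ValueError("fewer than 3 common genetic lines between platforms")
        restriction = f"common lines only (n={len(lines_keep)})"

    platforms = [meta_a.table["platform"].iloc[0], meta_b.table["platform"].iloc[0]]
    if platforms[0] == platforms[1]:
        platforms[1] = platforms[1] + "-2"  # disambiguate identical platform tags

    profiles: list[CorrelationProfile] = []
    for platform, (fm, meta, ph) in zip(platforms, ((fm_a, meta_a, ph_a),
                                                    (fm_b, meta_b, ph_b))):
        if lines_keep is not None:
            keep = meta.table["line_id"].isin(lines_keep)
            meta = SampleMeta(meta.table[keep].copy())
            fm = FeatureMatrix(fm.data[meta.sample_ids], fm.kind)
        lsm_f = ls_means(fm, meta, "line_diet")[feats]
        lsm_t = ls_means(ph, meta, "line_diet")[[trait]]
        for diet in meta.diets:
            prof = trait_correlations(lsm_f, lsm_t, scope=diet, method=method,
                                      platform=platform)[trait]
            profiles.append(prof)
    return conservation_matrix(profiles, restriction=restriction)
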