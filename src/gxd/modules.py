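"""Module summaries: first principal component, trait links, reaction norms.

Each retained module is summarised by the leading principal component of its
standardized member profiles (the module "eigengene").  That one-dimensional
score per line x diet unit is then correlated with the gross phenotypes,
pooled across diets or within each diet, and laid out as genotype-by-diet
reaction norms (one trajectory per genetic line across diets).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import nlp

log = logging.getLogger("gxd")

__all__ = ["ModulePC", "module_pc1", "correlate_module_traits", "reaction_norms"]


@dataclass
class ModulePC:
    """Leading principal component of a module's standardized members.

    Loadings are unit-norm with the sign fixed so their sum is >= 0
    (biological sign is arbitrary; the convention makes runs reproducible).
    ``variance_explained`` is the leading eigenvalue's share of total
    variance of the standardized member profiles.
    """

    module: int
    loadings: pd.Series
    scores: pd.Series
    variance_explained: float
    sign_convention: str = "sum_loadings_nonneg"


def module_pc1(lsm: pd.DataFrame, members: list[str], module: int = 1) -> ModulePC:
    """PC1 of the member features over grouping units.

    Member profiles are standardized (zero mean, unit variance across units)
    before the eigen-decomposition, so every member enters with equal weight.
    Constant members are dropped with a warning; fewer than 2 usable members
    is an error.
    """
    missing = [m for m in members if m not in lsm.columns]
    if missing:
        raise KeyError(f"module members absent from LS-means table: {missing[:10]}")
    X = lsm[list(members)].dropna(axis=0, how="any")
    if len(X) < 3:
        raise ValueError("need at least 3 complete units for PCA")
    sd = X.std(ddof=1)
    const = sd.index[(sd == 0) | sd.isna()].tolist()
    if const:
        warnings.warn(f"dropping {len(const)} constant member(s) from module PC")
        X = X.drop(columns=const)
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 usable (non-constant) members")
    Z = (X - X.mean()) / X.std(ddof=1)
    # SVD of the standardized profile matrix: columns = members
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    load = Vt[0]
    if load.sum() < 0 or (load.sum() == 0 and load[np.flatnonzero(load)[0]] < 0):
        load = -load
        U = U.copy()
        U[:, 0] = -U[:, 0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    scores = pd.Series(U[:, 0] * s[0], index=X.index, name=f"module{module}_pc1")
    loadings = pd.Series(load, index=X.columns, name="loading")
    return ModulePC(
        module=module,
        loadings=loadings,
        scores=scores,
        variance_explained=var_explained,
    )


def correlate_module_traits(
    pc: ModulePC, traits: pd.DataFrame, per_diet: bool = False
) -> pd.DataFrame:
    """Correlate module PC1 scores with trait LS-means.

    ``traits`` is a units x traits table sharing the PC1 score index
    (line x diet cells).  With ``per_diet`` the correlation is computed
    within each diet separately (the diet level of the unit MultiIndex),
    otherwise pooled over all units.  Returns a tidy table
    (module, trait, diet, r, p, NLP, n); pairs with fewer than 3 common
    units are flagged not-computable (NaN r with n recorded).
    """
    common = pc.scores.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 common units between scores and traits")
    scores = pc.scores.loc[common]
    traits = traits.loc[common]

    def _one(sc: pd.Series, tr: pd.Series, diet: str) -> dict:
        mask = sc.notna() & tr.notna()
        n = int(mask.sum())
        if n < 3 or sc[mask].std() == 0 or tr[mask].std() == 0:
            return dict(module=pc.module, trait=tr.name, diet=diet,
                        r=np.nan, p=np.nan, NLP=np.nan, n=n)
        r, p = stats.pearsonr(sc[mask], tr[mask])
        return dict(module=pc.module, trait=tr.name, diet=diet,
                    r=float(r), p=float(p), NLP=float(nlp(max(p, 0.0))), n=n)

    rows = []
    for trait in traits.columns:
        rows.append(_one(scores, traits[trait], "pooled"))
        if per_diet:
            diets = scores.index.get_level_values("diet_id")
            for diet in dict.fromkeys(diets):
                sel = diets == diet
                rows.append(_one(scores[sel], traits[trait][sel], str(diet)))
    return pd.DataFrame(rows)


def reaction_norms(pc: ModulePC) -> pd.DataFrame:
    """Line x diet table of mean PC1 scores (genotype-by-diet reaction norms).

    Scores must be indexed by (line_id, diet_id) units; missing cells come
    out as NaN.
    """
    idx = pc.scores.index
    if not isinstance(idx, pd.MultiIndex) or "line_id" not in idx.names or "diet_id" not in idx.names:
        raise ValueError("PC1 scores must be indexed by (line_id, diet_id) units")
    norms = (
        pc.scores.groupby([idx.get_level_values("line_id"), idx.get_level_values("diet_id")])
        .mean()
        .unstack("diet_id")
    )
    # preserve diet appearance order from the score index
    diet_order = list(dict.fromkeys(idx.get_level_values("diet_id")))
    return norms[diet_order]
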