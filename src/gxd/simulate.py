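"""Synthetic factorial line x diet x replicate datasets with known truth.

The generator plants exactly the statistical structure the analysis stages
assume, so every downstream result can be checked against ground truth:

* per-feature variance components — each feature f in sample (i, j, m) is

      Y_fijm = mu_f + g_fi + d_fj + gamma_fij + lambda_f * M_k(f),ij + e_fijm

  with independent Gaussian draws g ~ N(0, var_G), d ~ N(0, var_D),
  gamma ~ N(0, var_GxD), e ~ N(0, var_E) scaled per feature class;
* planted modules — features sharing a latent factor M_k,ij (itself a sum
  of line, diet and line-x-diet Gaussian components) with loading lambda;
* diet-dependent trait construction — gross phenotypes for unit (i, j, m)
  are sum_k beta_kj * M_k,ij plus Gaussian noise, so "which features
  correlate with which trait on which diet" has unambiguous ground truth
  (the module members).

Identical spec (including its seed) gives bit-identical output; per-stage
substreams come from :mod:`gxd._rng` (PCG64).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .datatypes import FeatureMatrix, PhenotypeTable, SampleMeta, TRAIT_NAMES

log = logging.getLogger("gxd")

__all__ = [
    "FeatureClass",
    "ModuleSpec",
    "TraitSpec",
    "GeneratorSpec",
    "SyntheticTruth",
    "generate_dataset",
    "preset_scenario",
    "power_experiment",
    "loading_for_signal_share",
    "planted_module_trait_corr",
    "remeasure_platform",
    "PRESET_NAMES",
]


def loading_for_signal_share(share: float, factor_var: float, idio_var: float) -> float:
    """Loading lambda so the module factor carries ``share`` of a member's
    variance: lambda^2 * factor_var / (lambda^2 * factor_var + idio_var) = share.

    ``idio_var`` is the member's non-shared variance at the level where
    coherence is assessed (e.g. var_G + var_GxD + var_E / n_replicates for
    per-diet line means).  The expected within-module correlation equals
    ``share``.
    """
    if not (0 < share < 1):
        raise ValueError("share must lie in (0, 1)")
    if factor_var <= 0 or idio_var < 0:
        raise ValueError("factor_var must be > 0 and idio_var >= 0")
    return float(np.sqrt(share / (1.0 - share) * idio_var / factor_var))


@dataclass
class FeatureClass:
    """A block of features sharing planted variance components."""

    fraction: float
    var_G: float = 0.0
    var_D: float = 0.0
    var_GxD: float = 0.0
    var_E: float = 1.0

    def __post_init__(self) -> None:
        if min(self.var_G, self.var_D, self.var_GxD) < 0:
            raise ValueError("variance components must be >= 0")
        if self.var_E <= 0:
            raise ValueError("var_E must be > 0")
        if not (0 <= self.fraction <= 1):
            raise ValueError("class fraction must lie in [0, 1]")


@dataclass
class ModuleSpec:
    """A planted module: correlated features sharing one latent factor."""

    size: int
    loading: float
    factor_var_G: float = 1.0
    factor_var_D: float = 0.0
    factor_var_GxD: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if min(self.factor_var_G, self.factor_var_D, self.factor_var_GxD) < 0:
            raise ValueError("factor variances must be >= 0")
        if self.factor_var_G + self.factor_var_D + self.factor_var_GxD <= 0:
            raise ValueError("module factor needs positive total variance")

    @property
    def factor_var(self) -> float:
        return self.factor_var_G + self.factor_var_D + self.factor_var_GxD


@dataclass
class TraitSpec:
    """Per-diet loading vector over module factors plus trait noise."""

    loadings: dict[str, tuple[float, ...]]  # diet -> beta per module
    noise_var: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_var <= 0:
            raise ValueError("trait noise_var must be > 0")
        self.loadings = {d: tuple(float(b) for b in v) for d, v in self.loadings.items()}


@dataclass
class GeneratorSpec:
    n_lines: int
    diets: list[str]
    n_replicates: int
    n_features: int
    feature_classes: list[FeatureClass]
    modules: list[ModuleSpec] = field(default_factory=list)
    trait_specs: dict[str, TraitSpec] = field(default_factory=dict)
    seed: int = 0
    mu: float = 0.0
    block_var: float = 0.0  # optional replicate-block main effect, default off
    fixed_diet_effects: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_replicates < 1 or self.n_features < 1:
            raise ValueError("n_lines, n_replicates and n_features must be >= 1")
        if not self.diets:
            raise ValueError("at least one diet required")
        total = sum(c.fraction for c in self.feature_classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"feature class fractions must sum to 1 (got {total})")
        if sum(m.size for m in self.modules) > self.n_features:
            raise ValueError("module sizes exceed n_features")
        for trait, ts in self.trait_specs.items():
            for diet, beta in ts.loadings.items():
                if diet not in self.diets:
                    raise ValueError(f"trait {trait!r} loads unknown diet {diet!r}")
                if len(beta) != len(self.modules):
                    raise ValueError(
                        f"trait {trait!r} loading vector length {len(beta)} "
                        f"!= number of modules {len(self.modules)}"
                    )
        if self.block_var < 0:
            raise ValueError("block_var must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_lines * len(self.diets) * self.n_replicates


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, serializable as JSON text."""

    features: pd.DataFrame          # per feature: class_index, var_G/D/GxD/E, module, loading
    factors: dict[int, pd.DataFrame]  # module -> line x diet factor realisations
    betas: dict[str, pd.DataFrame]  # trait -> diet x module loading matrix
    seed: int

    def module_members(self, module: int) -> list[str]:
        return self.features.index[self.features["module"] == module].tolist()

    @property
    def module_map(self) -> pd.Series:
        return self.features["module"]

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "seed": self.seed,
            "features": self.features.reset_index().to_dict(orient="list"),
            "factors": {
                str(k): {"index": df.index.tolist(), "columns": df.columns.tolist(),
                         "values": df.to_numpy().tolist()}
                for k, df in self.factors.items()
            },
            "betas": {
                t: {"index": df.index.tolist(), "columns": [str(c) for c in df.columns],
                    "values": df.to_numpy().tolist()}
                for t, df in self.betas.items()
            },
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "SyntheticTruth":
        if text_or_path.lstrip().startswith("{"):
            payload = json.loads(text_or_path)
        else:
            with open(text_or_path, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        feats = pd.DataFrame(payload["features"]).set_index("feature_id")
        factors = {
            int(k): pd.DataFrame(v["values"], index=v["index"], columns=v["columns"])
            for k, v in payload["factors"].items()
        }
        betas = {
            t: pd.DataFrame(v["values"], index=v["index"],
                            columns=[int(c) for c in v["columns"]])
            for t, v in payload["betas"].items()
        }
        return cls(features=feats, factors=factors, betas=betas, seed=int(payload["seed"]))


def _class_counts(fractions: list[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n features over class fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts


def generate_dataset(
    spec: GeneratorSpec,
) -> tuple[FeatureMatrix, SampleMeta, PhenotypeTable, SyntheticTruth]:
    """Draw one dataset from the generating model (bit-reproducible)."""
    L, J, R, F = spec.n_lines, len(spec.diets), spec.n_replicates, spec.n_features
    lines = [f"L{i + 1:03d}" for i in range(L)]
    reps = [f"R{m + 1}" for m in range(R)]

    # sample metadata (line-major, diet, then replicate block)
    rows = [
        (f"{ln}.{dt}.{rp}", ln, dt, rp, "microarray")
        for ln in lines for dt in spec.diets for rp in reps
    ]
    meta = SampleMeta(pd.DataFrame(rows, columns=["sample_id", "line_id", "diet_id",
                                                  "replicate_id", "platform"]))

    # per-feature class assignment (contiguous blocks, spec order)
    counts = _class_counts([c.fraction for c in spec.feature_classes], F)
    class_idx = np.repeat(np.arange(len(counts)), counts)
    var = {
        comp: np.array([getattr(spec.feature_classes[c], f"var_{comp}") for c in class_idx])
        for comp in ("G", "D", "GxD", "E")
    }

    rng_f = stage_rng(spec.seed, "features")
    g = rng_f.standard_normal((F, L)) * np.sqrt(var["G"])[:, None]
    d = rng_f.standard_normal((F, J)) * np.sqrt(var["D"])[:, None]
    gxd = rng_f.standard_normal((F, L, J)) * np.sqrt(var["GxD"])[:, None, None]
    eps = rng_f.standard_normal((F, L, J, R)) * np.sqrt(var["E"])[:, None, None, None]

    Y = spec.mu + g[:, :, None, None] + d[:, :, None, None].transpose(0, 2, 1, 3) + \
        gxd[:, :, :, None] + eps
    if spec.fixed_diet_effects:
        shift = np.array([spec.fixed_diet_effects.get(dt, 0.0) for dt in spec.diets])
        Y += shift[None, None, :, None]

    # module factors and member loadings
    rng_m = stage_rng(spec.seed, "factors")
    module_of = np.zeros(F, dtype=int)  # 0 = no module
    loading = np.zeros(F)
    factors: dict[int, pd.DataFrame] = {}
    start = 0
    for k, mod in enumerate(spec.modules, start=1):
        a = rng_m.standard_normal(L) * np.sqrt(mod.factor_var_G)
        b = rng_m.standard_normal(J) * np.sqrt(mod.factor_var_D)
        c = rng_m.standard_normal((L, J)) * np.sqrt(mod.factor_var_GxD)
        M = a[:, None] + b[None, :] + c
        factors[k] = pd.DataFrame(M, index=lines, columns=spec.diets)
        members = slice(start, start + mod.size)
        module_of[members] = k
        loading[members] = mod.loading
        Y[members] += mod.loading * M[None, :, :, None]
        start += mod.size

    rng_b = stage_rng(spec.seed, "blocks")
    if spec.block_var > 0:
        block = rng_b.standard_normal(R) * np.sqrt(spec.block_var)
        Y += block[None, None, None, :]

    feature_ids = [f"F{i + 1:05d}" for i in range(F)]
    data = pd.DataFrame(Y.reshape(F, -1), index=pd.Index(feature_ids, name="feature_id"),
                        columns=meta.sample_ids)
    fm = FeatureMatrix(data)

    # gross phenotypes, driven only through module factors
    rng_t = stage_rng(spec.seed, "traits")
    trait_specs = dict(spec.trait_specs)
    for t in TRAIT_NAMES:  # every dataset carries the three standard traits
        if t not in trait_specs:
            trait_specs[t] = TraitSpec(
                loadings={dt: tuple(0.0 for _ in spec.modules) for dt in spec.diets},
                noise_var=1.0,
            )
    pheno = {}
    betas: dict[str, pd.DataFrame] = {}
    for trait, ts in trait_specs.items():
        beta = pd.DataFrame(
            [[ts.loadings.get(dt, tuple(0.0 for _ in spec.modules))[k - 1]
              for k in factors] for dt in spec.diets],
            index=spec.diets, columns=list(factors),
        ) if factors else pd.DataFrame(index=spec.diets, columns=[])
        betas[trait] = beta
        score = np.zeros((L, J))
        for k, M in factors.items():
            score += beta[k].to_numpy()[None, :] * M.to_numpy()
        vals = score[:, :, None] + rng_t.standard_normal((L, J, R)) * np.sqrt(ts.noise_var)
        pheno[trait] = vals.reshape(-1)
    ph = PhenotypeTable(pd.DataFrame(pheno, index=pd.Index(meta.sample_ids, name="unit_id")))

    truth_feats = pd.DataFrame(
        {
            "class_index": class_idx,
            "var_G": var["G"], "var_D": var["D"], "var_GxD": var["GxD"], "var_E": var["E"],
            "module": module_of,
            "loading": loading,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    truth = SyntheticTruth(features=truth_feats, factors=factors, betas=betas, seed=spec.seed)
    log.info("generate_dataset: %d features x %d samples (%d lines x %d diets x %d reps)",
             F, spec.n_samples, L, J, R)
    return fm, meta, ph, truth


# ---------------------------------------------------------------------------
# preset scenarios

PRESET_NAMES = ("reed2015_main", "reed2015_followup", "conserved", "cryptic",
                "null", "stepwise")

_FOUR_DIETS = ["normal", "control", "high_sugar", "high_fat"]
_TWO_DIETS = ["control", "high_fat"]


def _zero_loadings(diets: list[str], n_modules: int) -> dict[str, tuple[float, ...]]:
    return {dt: tuple(0.0 for _ in range(n_modules)) for dt in diets}


def _main_preset(n_features: int, seed: int) -> GeneratorSpec:
    """Main factorial design: 20 lines x 4 diets x 3 replicate blocks.

    Feature classes plant strong genetic, dietary and interaction variance
    next to a pure-noise class; four interaction-rich modules of 25 sit
    inside the interaction class, and the traits load on them (weight on
    module 1 with a planted line x diet correlation of 0.6; triglyceride on
    module 2 only on the high-sugar diet; sugar on modules 1 and 3).
    """
    if n_features < 125:
        raise ValueError("reed2015_main needs n_features >= 125 (4 modules of 25 "
                         "inside the 20% interaction class)")
    classes = [
        FeatureClass(fraction=0.20, var_GxD=2.0),   # interaction class (holds the modules)
        FeatureClass(fraction=0.25, var_G=2.0),     # strong genetic class
        FeatureClass(fraction=0.15, var_D=2.0),     # strong dietary class
        FeatureClass(fraction=0.40),                # pure-noise class
    ]
    fac = dict(factor_var_G=1.0, factor_var_D=0.5, factor_var_GxD=1.0)
    factor_var = sum(fac.values())
    idio = 0.0 + 2.0 + 1.0 / 3.0  # var_G + var_GxD + var_E / n_reps at cell level
    lam = loading_for_signal_share(0.7, factor_var, idio)
    modules = [ModuleSpec(size=25, loading=lam, **fac) for _ in range(4)]

    # weight <- module 1 at planted cell-level correlation 0.6 on every diet
    rho = 0.6
    noise_w = 3.0 * factor_var * (1.0 / rho**2 - 1.0)
    z4 = _zero_loadings(_FOUR_DIETS, 4)
    traits = {
        "weight": TraitSpec({dt: (1.0, 0.0, 0.0, 0.0) for dt in _FOUR_DIETS}, noise_w),
        "triglyceride": TraitSpec({**z4, "high_sugar": (0.0, 1.0, 0.0, 0.0)}, 3.0),
        "sugar": TraitSpec({dt: (0.5, 0.0, 0.8, 0.0) for dt in _FOUR_DIETS}, 3.0),
    }
    return GeneratorSpec(
        n_lines=20, diets=list(_FOUR_DIETS), n_replicates=3, n_features=n_features,
        feature_classes=classes, modules=modules, trait_specs=traits, seed=seed,
    )


def _followup_preset(n_features: int, seed: int) -> GeneratorSpec:
    """Follow-up confirmation design: 45 lines x 2 diets x 2 replicates,
    45 assayed genes (180 samples)."""
    classes = [FeatureClass(fraction=0.5, var_G=1.0), FeatureClass(fraction=0.5)]
    fac = dict(factor_var_G=1.0, factor_var_D=0.0, factor_var_GxD=0.5)
    lam = loading_for_signal_share(0.8, 1.5, 1.0 + 0.0 + 1.0 / 2.0)
    modules = [ModuleSpec(size=10, loading=lam, **fac) for _ in range(3)]
    z = _zero_loadings(_TWO_DIETS, 3)
    traits = {
        "triglyceride": TraitSpec({dt: (1.0, 0.0, 0.0) for dt in _TWO_DIETS}, 0.5),
        "weight": TraitSpec(z, 1.0),
        "sugar": TraitSpec(z, 1.0),
    }
    return GeneratorSpec(
        n_lines=45, diets=list(_TWO_DIETS), n_replicates=2, n_features=n_features,
        feature_classes=classes, modules=modules, trait_specs=traits, seed=seed,
    )


def _conservation_preset(kind: str, n_features: int, seed: int) -> GeneratorSpec:
    """Shared scaffold of the conserved / cryptic / null scenarios.

    45 lines x 2 diets x 2 replicates, six modules of 60 features with a
    member signal share of 0.9 at the per-diet line-mean level.  Each trait
    loads one module: in `conserved` the same module on both diets, in
    `cryptic` orthogonal modules on the familiar (control) vs novel
    (high-fat) diet, and in `null` nothing at all.
    """
    if n_features < 360:
        raise ValueError(f"{kind} needs n_features >= 360 (6 modules of 60)")
    classes = [FeatureClass(fraction=1.0, var_G=0.5, var_E=1.0)]
    fac = dict(factor_var_G=1.0, factor_var_D=0.0, factor_var_GxD=0.5)
    within_diet_factor_var = fac["factor_var_G"] + fac["factor_var_GxD"]
    idio = 0.5 + 0.0 + 1.0 / 2.0  # var_G + var_GxD + var_E / n_reps, per-diet line means
    lam = loading_for_signal_share(0.9, within_diet_factor_var, idio)
    modules = [ModuleSpec(size=60, loading=lam, **fac) for _ in range(6)]

    def beta(module: int) -> tuple[float, ...]:
        return tuple(1.0 if k == module else 0.0 for k in range(1, 7))

    familiar, novel = _TWO_DIETS
    if kind == "conserved":
        traits = {
            "weight": TraitSpec({familiar: beta(1), novel: beta(1)}, 0.25),
            "triglyceride": TraitSpec({familiar: beta(2), novel: beta(2)}, 0.25),
            "sugar": TraitSpec({familiar: beta(3), novel: beta(3)}, 0.25),
        }
    elif kind == "cryptic":
        traits = {
            "weight": TraitSpec({familiar: beta(1), novel: beta(4)}, 0.25),
            "triglyceride": TraitSpec({familiar: beta(2), novel: beta(5)}, 0.25),
            "sugar": TraitSpec({familiar: beta(3), novel: beta(6)}, 0.25),
        }
    else:  # null: no trait is driven by any module
        traits = {t: TraitSpec(_zero_loadings(_TWO_DIETS, 6), 1.0) for t in TRAIT_NAMES}
    return GeneratorSpec(
        n_lines=45, diets=list(_TWO_DIETS), n_replicates=2, n_features=n_features,
        feature_classes=classes, modules=modules, trait_specs=traits, seed=seed,
    )


def _stepwise_preset(seed: int) -> GeneratorSpec:
    """Minimal-predictor-selection scenario: 80 iid units, 50 candidates.

    Three single-feature modules are the true predictors (standardized
    effect ~0.5 on weight); the 47 distractors form two coherent modules
    (share 0.95) so they carry realistic co-expression structure.
    Triglyceride and sugar load nothing (selection-null traits).
    """
    lam = loading_for_signal_share(0.95, 1.0, 1.0)
    modules = (
        [ModuleSpec(size=1, loading=lam) for _ in range(3)]
        + [ModuleSpec(size=24, loading=lam), ModuleSpec(size=23, loading=lam)]
    )
    traits = {
        "weight": TraitSpec({"control": (0.5, 0.5, 0.5, 0.0, 0.0)}, 0.25),
        "triglyceride": TraitSpec({"control": (0.0,) * 5}, 1.0),
        "sugar": TraitSpec({"control": (0.0,) * 5}, 1.0),
    }
    return GeneratorSpec(
        n_lines=80, diets=["control"], n_replicates=1, n_features=50,
        feature_classes=[FeatureClass(fraction=1.0, var_E=1.0)],
        modules=modules, trait_specs=traits, seed=seed,
    )


def preset_scenario(name: str, n_features: int | None = None, seed: int = 0) -> GeneratorSpec:
    """Named study scenarios with planted structure.

    ``reed2015_main``: 20 lines x 4 diets x 3 replicates (240 samples),
    default 500 features (configurable up to the full 11650).
    ``reed2015_followup``: 45 lines x 2 diets x 2 replicates x 45 features
    (180 samples).  ``conserved`` / ``cryptic`` / ``null``: the trait
    loadings are identical across diets / orthogonal between the familiar
    and novel diet / all zero.  ``stepwise``: minimal-predictor scenario.
    """
    if name == "reed2015_main":
        return _main_preset(n_features or 500, seed)
    if name == "reed2015_followup":
        return _followup_preset(n_features or 45, seed)
    if name in ("conserved", "cryptic", "null"):
        return _conservation_preset(name, n_features or 500, seed)
    if name == "stepwise":
        return _stepwise_preset(seed)
    raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(PRESET_NAMES)}")


def planted_module_trait_corr(spec: GeneratorSpec, trait: str, module: int,
                              diet: str | None = None) -> float:
    """Construction-level correlation between module factor and trait at the
    line x diet cell level (trait noise averaged over replicates).

    Valid for a diet where the loading vector is defined; for traits with
    identical loadings across diets this is also the pooled value.
    """
    ts = spec.trait_specs[trait]
    dt = diet or spec.diets[0]
    beta = ts.loadings[dt]
    vks = [m.factor_var for m in spec.modules]
    vk = vks[module - 1]
    bk = beta[module - 1]
    trait_var = sum(b**2 * v for b, v in zip(beta, vks)) + ts.noise_var / spec.n_replicates
    if trait_var <= 0 or vk <= 0:
        return 0.0
    return float(bk * vk / (np.sqrt(vk) * np.sqrt(trait_var)))


def remeasure_platform(
    fm: FeatureMatrix, meta: SampleMeta, noise_share: float,
    platform: str = "qpcr", seed: int = 0,
) -> tuple[FeatureMatrix, SampleMeta]:
    """Simulate an independent platform re-measurement of the same samples.

    Adds per-feature Gaussian noise so that a fraction ``noise_share`` of
    each re-measured feature's variance is platform noise (attenuating all
    correlations by sqrt(1 - noise_share) in expectation).
    """
    if not (0 <= noise_share < 1):
        raise ValueError("noise_share must lie in [0, 1)")
    rng = stage_rng(seed, "platform")
    vals = fm.values()
    sd = vals.std(axis=1, ddof=1)
    scale = sd * np.sqrt(noise_share / (1.0 - noise_share))
    noisy = vals + rng.standard_normal(vals.shape) * scale[:, None]
    fm_b = FeatureMatrix(pd.DataFrame(noisy, index=fm.data.index, columns=fm.data.columns),
                         fm.kind)
    tab = meta.table.copy()
    tab["platform"] = platform
    return fm_b, SampleMeta(tab)


def power_experiment(
    spec: GeneratorSpec,
    replicate_grid: list[int],
    n_sims: int,
    alpha: float = 0.05,
    detection: str = "fdr",
) -> pd.DataFrame:
    """Detection power for the genotype-by-diet effect vs replicate count.

    For each replicate count the scenario is re-simulated ``n_sims`` times
    and the fraction of features with planted interaction variance
    (class var_GxD or a loaded interaction-bearing factor) detected at
    level ``alpha`` is recorded with its binomial standard error.
    ``detection="fdr"`` counts q_GxD <= alpha; ``detection="raw"`` counts
    p_GxD < alpha (the false-positive rate under a null spec).
    """
    from .anova import fit_gxd_anova  # local import: avoids a cycle at import time

    if not replicate_grid:
        raise ValueError("replicate_grid must be nonempty")
    if any(g < 2 for g in replicate_grid):
        raise ValueError("replicate counts must be >= 2 "
                         "(interaction inestimable with < 2 replicates per cell)")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if detection not in ("fdr", "raw"):
        raise ValueError("detection must be 'fdr' or 'raw'")

    rows = []
    for gi, n_rep in enumerate(replicate_grid):
        hits = 0
        total = 0
        for si in range(n_sims):
            sub_seed = int(stage_rng(spec.seed, "power", gi, si).integers(2**31))
            sub = dataclasses.replace(spec, n_replicates=int(n_rep), seed=sub_seed)
            fm, meta, _, truth = generate_dataset(sub)
            res = fit_gxd_anova(fm, meta)
            planted = truth.features["var_GxD"].to_numpy().copy()
            for k, mod in enumerate(sub.modules, start=1):
                if mod.factor_var_GxD > 0:
                    members = truth.features["module"] == k
                    planted[members.to_numpy()] += (
                        truth.features.loc[members, "loading"] ** 2 * mod.factor_var_GxD
                    )
            target = planted > 0
            if not target.any():
                target = np.ones(len(planted), dtype=bool)  # null spec: FPR calibration
            if detection == "fdr":
                detected = res.table["q_GxD"].to_numpy() <= alpha
            else:
                detected = res.table["p_GxD"].to_numpy() < alpha
            hits += int(detected[target].sum())
            total += int(target.sum())
        power = hits / total
        se = float(np.sqrt(power * (1 - power) / total))
        rows.append(dict(n_replicates=int(n_rep), power=float(power), se=se,
                         n_detected=hits, n_evaluated=total, n_sims=n_sims))
    out = pd.DataFrame(rows)
    log.info("power_experiment (%s, alpha=%g):\n%s", detection, alpha, out)
    return out
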