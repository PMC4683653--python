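# gxd — genotype-by-diet endophenotype analysis

`gxd` is a toolkit for dissecting how genetic variation, diet, and their
interaction shape molecular intermediate phenotypes (transcript and
metabolite abundances, "endophenotypes") and how those endophenotypes link
to gross metabolic traits — pupal weight, larval triglyceride and total
sugar — in factorial *line × diet × replicate* designs such as panels of
inbred *Drosophila* lines raised on contrasting diets.

It is written for quantitative/systems geneticists who have a normalized
feature × sample abundance matrix, sample annotation (genetic line, diet,
replicate block, platform), and unit-level gross phenotypes, and who want
the full chain of analyses:

1. **Variance partitioning.** Each feature is fitted with the fixed-effects
   two-way model `Y_ijm = μ + G_i + D_j + (G×D)_ij + ε_ijm`; Type III sums
   of squares, F ratios against MS_E, per-effect Benjamini–Hochberg
   q-values, and a Venn-style partition of significant effect subsets.
2. **Module detection.** Features passing a significance filter are
   clustered by adaptive-sharpening modularity maximization: edge weights
   `w_ij(s) = |r_ij|^s` over line×diet least-squares means, spectral
   (leading-eigenvector) bisection with greedy refinement, sharpness `s`
   chosen to maximize Newman–Girvan modularity `Q`. Modules are ordered by
   average within-module |r| and filtered by size/coherence.
3. **Module–trait mapping.** Each module is summarized by the first
   principal component of its standardized members (the "eigengene");
   PC1 scores are correlated with traits pooled and per diet, and laid out
   as genotype-by-diet reaction norms.
4. **Trait correlates and minimal predictors.** Per-feature trait
   correlation profiles (r, p, NLP = −log10 p per feature), multi-trait and
   multi-diet overlap counts, and forward stepwise regression with
   `BIC = n·ln(RSS/n) + k·ln(n)` for a minimal explanatory feature set.
5. **Conservation ("co-correlation").** The second-order Pearson
   correlation between two conditions' feature–trait correlation vectors,
   across traits, diets and measurement platforms, plus a permutation test
   for whether significant correlate sets are shared across diets more than
   chance expects. A collapse of cross-diet co-correlation on a novel diet
   is the signature of cryptic variation exposed by decanalization.
6. **Synthetic data with ground truth.** A generator that plants variance
   components, correlated-feature modules (latent line/diet/line×diet
   factors with chosen loadings) and diet-dependent trait loadings, so
   every stage above can be validated against known truth — including
   `conserved`, `cryptic` and `null` scenarios and a power study for the
   interaction effect.

## Worked example

```python
import pandas as pd
from gxd import (preset_scenario, generate_dataset, GxDAnova, ls_means,
                 feature_correlations, mmc, module_pc1, correlate_module_traits)

spec = preset_scenario("reed2015_main", seed=1)   # 20 lines x 4 diets x 3 reps
fm, meta, ph, truth = generate_dataset(spec)

res = GxDAnova(fm, meta).fit()
print(res.summary(3))

gxd_hits = res.significant("GxD", q_threshold=0.05)
lsm = ls_means(fm, meta, "line_diet")
part = mmc(feature_correlations(lsm, gxd_hits))
print(part.summary())

traits = ls_means(ph, meta, "line_diet")
links = pd.concat(
    correlate_module_traits(module_pc1(lsm, part.members(m), module=m), traits)
    for m in part.retained_modules())
print(links[links.p < 0.01].to_string(index=False))
```

prints

```
Two-way G x D ANOVA: 500 features, 20 lines x 4 diets, n=240
significant at FDR 0.05: G=228, D=174, GxD=104
             F_G       p_G       q_G   F_D       p_D       q_D  F_GxD     p_GxD     q_GxD
feature_id
F00097     54.14 1.285e-59 9.179e-58 121.7 4.313e-41 4.792e-40  19.83 2.554e-49 1.277e-46
F00095     48.51 2.122e-56 7.577e-55 182.7 1.884e-51 5.542e-50  18.47  2.78e-47  6.95e-45
F00054     28.87 4.752e-42  2.22e-41 6.748 0.0002581 0.0007867   18.1 1.057e-46 1.762e-44

Modularity clustering: 104 features, 4 modules (Q=0.7023, s=4, transform=power)
        size  avg_abs_corr  original_index  excluded
module
1         26         0.695               1     False
2         25         0.628               2     False
3         25         0.577               3     False
4         28         0.547               4     False

 module  trait   diet        r            p       NLP  n
      3  sugar pooled 0.687860 1.806730e-12 11.743107 80
      4 weight pooled 0.586910 1.055395e-08  7.976585 80
      4  sugar pooled 0.458546 1.889895e-05  4.723562 80
```

Reading this: the scenario plants four interaction-rich modules of 25
features inside a 100-feature genotype-by-diet class. The ANOVA recovers
the planted classes (104 interaction-significant features at FDR 0.05 of
100 planted), clustering splits them into exactly four modules at sharpness
s = 4 with modularity Q = 0.70, and the module eigengenes recover the
planted trait links on the n = 80 line×diet means: one module drives weight
(planted construction-level correlation 0.6, observed 0.587) and also loads
sugar, another drives sugar only. Module indices order by coherence, so
which planted module lands at which index varies by realization.

The same pipeline is available from the shell:

```sh
gxd simulate --scenario cryptic --seed 7 --out run/
gxd anova --out run/
gxd cluster --filter gxd-significant --out run/
gxd module-trait --out run/
gxd correlate --out run/ --per-diet
gxd stepwise --out run/
gxd conserve --out run/
```

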