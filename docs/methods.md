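# Methods

## The model

Every feature (a transcript or metabolite abundance, normalized and treated
as continuous) is analysed with the fixed-effects two-way linear model

    Y_ijm = mu + G_i + D_j + (GxD)_ij + e_ijm,

where `G_i` is the genetic line, `D_j` the diet, `(GxD)_ij` their
interaction and `e_ijm ~ N(0, sigma^2)` the residual of the m-th replicate
sample. Lines and diets are fixed effects: the inference target is the set
of sampled lines and diets themselves, not a population of lines, and no
random terms or REML machinery are used. Sums of squares are Type III,
computed as full-versus-reduced residual comparisons under sum-to-zero
coding, so mildly unbalanced designs (missing samples) are handled; on
balanced complete designs they coincide with the classical sequential
decomposition and `SS_G + SS_D + SS_GxD + SS_E = SS_total` to relative
1e-8. F ratios are taken against the residual mean square, p-values from
the F distribution, and NLP = −log10 p (p floored at 1e-300 so NLP stays
finite).

Multiplicity is controlled per effect across features with the
Benjamini–Hochberg step-up: `q_(i) = min_{j>=i} m·p_(j)/j`, mapped back to
input order; ties share the q of their sorted position. FDR is applied per
effect rather than pooled because the effect-specific significant lists are
the downstream filtering units.

**Correlation units.** All correlation-type analyses operate on
least-squares means. On balanced designs these equal arithmetic cell means;
on unbalanced data the mean of observed values within each nonempty cell
(the saturated model's prediction) is used and empty cells are dropped with
a warning. The default grouping is line×diet (n = 80 units for the
20-line × 4-diet design); line×diet×replicate (n = 240) is available via
`replicate_collapse` because the two conventions are both defensible and
differ in effective n — outputs always record the n actually used.

## Modularity clustering

Filtered feature sets (interaction-significant features, or features
correlated with a trait at P < 0.01) are clustered on their pairwise
correlation structure. The adaptive transform `w_ij(s) = |r_ij|^s` (i ≠ j,
zero diagonal) sharpens the contrast between strong and weak correlations;
for each s on a grid (default 1..30) the weighted graph is partitioned by
leading-eigenvector spectral bisection of the modularity matrix
`B_ij = w_ij − k_i k_j / 2W`, each bisection refined by greedy
single-feature moves until no move increases Q, with splitting stopped when
the best split's ΔQ ≤ 0. The sharpness maximizing Q is kept (ties toward
the smallest s). Absolute correlation is used so strongly negatively
correlated features join the same module. An alternative logistic weighting
`1/(1+exp(−(|r|−tau)/sigma))` is provided as a config-swappable strategy.

Numerical conventions making runs exactly reproducible: eigenvectors come
from `numpy.linalg.eigh` with the sign fixed so the largest-magnitude
component is positive; greedy refinement visits features in index order and
accepts only strictly positive gains (> 1e-13). Modules are re-indexed by
descending average within-module |r| ("average degree of correlation"), so
module 1 is always the most coherent; retention filters (default: >= 3
members, average |r| > 0.5, with >= 15 members used for the large
trait-correlate runs) flag modules as excluded without renumbering the
rest. A graph with all-zero weights yields a single module with Q = 0 and
a warning rather than an error.

## Module summaries and trait links

A module's eigengene is the first principal component of its standardized
member profiles (zero mean, unit variance per member across units), so
high-variance members do not dominate; standardization also matches the
correlation-based module definition. Loadings are unit-norm with sign fixed
by `sum(loadings) >= 0` — biological sign is arbitrary, the convention only
makes reaction-norm plots reproducible. `variance_explained` is the leading
eigenvalue share and is always >= 1/size. PC1 scores are correlated with
trait LS-means pooled (n = lines × diets) and per diet (n = lines), with
two-sided p from the t distribution on n − 2 df; both n's are reported
explicitly since the two conventions are easily conflated.

## Trait correlates, overlap and minimal predictors

Per-feature trait correlations use Pearson (Spearman optional) on matched
units, p two-sided from t with n − 2 df; raw P thresholds (primary 0.01,
secondary 0.05) rather than FDR are used here, mirroring the convention for
correlate screens at these scales. Overlap accounting is exact per-subset
counting of significant features across conditions.

Forward stepwise regression starts from the intercept-only model, and at
each step adds the candidate minimizing `BIC = n·ln(RSS/n) + k·ln(n)` with
k counting slope terms plus intercept, stopping when no addition lowers BIC
strictly; ties break toward lexicographically smaller feature ids, and
candidates collinear with the selected set (R^2 >= 1 − 1e-10) are skipped
with a warning. The operation's contract restricts candidates to features
significantly correlated with the trait (`prefilter_p`, default pipeline
value 0.01); this prefilter materially controls false entries — greedy
search over many unfiltered independent candidates would enter noise
predictors at these n's, which is a property of BIC forward selection
itself, not of the implementation.

## Conservation statistics

The conservation ("co-correlation") statistic between two conditions is
the Pearson correlation of their per-feature trait-correlation vectors over
common features (matched by exact feature id). The analytic p uses n =
number of common features and therefore treats features as independent —
which co-expressed features violate — so it is best read as a ranking
device; an exact-label caveat is attached and a unit-resampling alternative
can be built from the profile machinery when calibrated p's matter. NLP
values are capped at 312 in reports only when p underflows double
precision; the underlying p is stored as 0-flagged.

The chance-sharing null draws independent uniform same-size feature sets
from the universe; the excess-sharing statistic is the count of features
significant in >= 2 conditions, with one-sided permutation p
`(1 + #{perm >= obs}) / (n_perm + 1)`. The null pairwise overlap mean
matches the hypergeometric expectation k1·k2/N.

Cross-platform conservation builds per-(platform, diet) profiles on shared
features (optionally restricted to shared genetic lines) and returns the
full co-correlation matrix; both all-lines and common-lines variants exist
because which lines enter each vector is a genuine analysis choice.

## The synthetic-data generator

The generator emulates factorial designs of inbred lines raised on
contrasting diets in replicate blocks. Feature f in sample (i, j, m) is

    Y_fijm = mu_f + g_fi + d_fj + gamma_fij + lambda_f · M_k(f),ij + e_fijm

with all draws independent Gaussians: `g ~ N(0, var_G)`,
`d ~ N(0, var_D)`, `gamma ~ N(0, var_GxD)`, `e ~ N(0, var_E)` per feature
class, and module factors `M_k,ij = a_ki + b_kj + c_kij` with their own
line/diet/interaction variances. Normality is an assumption of
convenience matched to the F-test machinery downstream; diet effects are
drawn as random deviates because only the variance structure matters for
recovery tests (a `fixed_diet_effects` override exists for reproducing
stark deterministic diet responses). Traits are driven **only** through
module factors plus Gaussian noise — never through direct single-feature
paths — so "which features correlate with which trait" has unambiguous
ground truth (the module members). Replicate blocks confound time in the
emulated designs; an optional block main effect is available but off by
default because the analysis model contains no block term.

Module loadings are set through the signal share: lambda is chosen so the
factor carries a stated fraction of member variance at the level where
coherence is assessed (`loading_for_signal_share`), making the expected
within-module correlation equal the share.

Determinism: all draws derive from per-stage PCG64 substreams keyed by
(seed, stage-name, CRC32), so identical specs give bit-identical TSV output
and stages are reorderable.

### Preset scenarios

* `reed2015_main` — 20 lines × 4 diets (normal, control, high-sugar,
  high-fat) × 3 replicate blocks, 240 samples. Default 500 features
  (configurable up to the full 11,650; 500 keeps the suite fast while
  leaving every class tens to hundreds of members): 20% interaction class
  (var_GxD = 2, holding four 25-member modules at signal share 0.7),
  25% genetic class (var_G = 2), 15% dietary class (var_D = 2), 40% pure
  noise; var_E = 1 throughout. Weight loads module 1 on every diet at a
  planted line×diet-level correlation of 0.6; triglyceride loads module 2
  on the high-sugar diet only; sugar loads modules 1 and 3.
* `reed2015_followup` — 45 lines × 2 diets × 2 replicates × 45 features
  (180 samples); triglyceride driven by one of three 10-member modules
  identically on both diets.
* `conserved` / `cryptic` / `null` — 45 lines × 2 diets × 2 replicates,
  500 features, six 60-member modules at per-diet signal share 0.9, trait
  noise variance 0.25. Each trait loads exactly one module: the same module
  on both diets (conserved), orthogonal modules on the familiar vs novel
  diet (cryptic — the loading vectors' dot product is exactly 0), or none
  (null). Design-stage simulation put the expected cross-diet
  co-correlation at ~0.89 (conserved) and ~−0.1 (cryptic), comfortably
  either side of the 0.4 classification threshold.
* `stepwise` — 80 iid units (80 lines × 1 diet × 1 replicate), 50
  candidate features: three single-feature modules are the true predictors
  (standardized effect ~0.5 on weight, trait noise SD 0.5) and the 47
  distractors form two coherent modules at share 0.95, giving the candidate
  pool realistic co-expression structure; triglyceride and sugar load
  nothing and serve as selection nulls.

### What the generator does and does not emulate

It reproduces the variance decomposition, module structure, diet-dependent
trait coupling, platform-noise attenuation (`remeasure_platform` adds a
chosen noise share) and design dimensions of real line-panel experiments.
It does **not** emulate microarray probe effects or intensity distributions,
GC-MS peak shapes, heavy-tailed or skewed abundance distributions,
missing-sample patterns, batch trends, or nutrient biochemistry. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the model's own assumptions — not robustness to every
pathology of real omics data; the Spearman option and the validator's
imbalance report are the first lines of defence there.

## Problem sizes and runtime choices

The shipped tests and acceptance script run the scenarios at their default
scaled-down sizes (500 features for the main and conservation scenarios,
20–100 seeds for the recovery-rate estimates), which we chose so the whole
suite completes in well under a minute on a laptop while every estimate
retains enough replication for its stated margin (binomial SEs of a few
percent). The full-size 11,650-feature design runs through the identical
code path via `preset_scenario("reed2015_main", n_features=11650)`.

## Known limitations

* The ANOVA excludes features only for numerically zero variance; heavy
  non-normality is the user's responsibility (Spearman correlations are
  available, rank-based ANOVA is not).
* Modularity clustering assigns every feature to a module; there is no
  "unassigned" state. Tiny or incoherent modules are expected to be hidden
  by the retention filter, not prevented.
* The spectral heuristic does not guarantee the global Q optimum; the
  brute-force Q evaluation used in the tests checks the reported Q of the
  found partition, not global optimality.
* The co-correlation analytic p inherits the feature-independence
  assumption discussed above.
* `ls_means` on unbalanced data equals observed nonempty-cell means; no
  imputation of empty cells is attempted anywhere.
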