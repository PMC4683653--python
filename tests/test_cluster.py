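import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gxd import (
    CorrelationMatrix,
    ModulePartition,
    feature_correlations,
    filter_by_factor,
    mmc,
    modularity_q,
    order_and_filter_modules,
)


def brute_force_q(W, labels):
    """Independent modularity evaluation: explicit per-module sums."""
    k = W.sum(axis=0)
    tot = k.sum()
    q = 0.0
    for lab in set(labels):
        idx = [i for i, l in enumerate(labels) if l == lab]
        w_in = sum(W[i, j] for i in idx for j in idx)
        q += w_in / tot - (sum(k[i] for i in idx) / tot) ** 2
    return q


def block_corr_matrix(blocks, within, between, seed=0, jitter=0.0):
    """Exact or jittered block-structured correlation matrix."""
    n = sum(blocks)
    labels = np.repeat(np.arange(len(blocks)), blocks)
    r = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, jitter, (n, n))
        r += np.triu(noise, 1) + np.triu(noise, 1).T
        r = np.clip(r, -0.99, 0.99)
    np.fill_diagonal(r, 1.0)
    ids = [f"f{i}" for i in range(n)]
    return CorrelationMatrix(ids, r), labels


def sample_module_data(rng, n_units, sizes, share, between_rho=0.0):
    """Draw unit x feature data with planted latent-factor modules."""
    K = len(sizes)
    common = rng.normal(size=n_units)
    factors = (np.sqrt(between_rho) * common[:, None]
               + np.sqrt(1 - between_rho) * rng.normal(size=(n_units, K)))
    cols = []
    lam = np.sqrt(share / (1 - share))
    for k, sz in enumerate(sizes):
        cols.append(lam * factors[:, [k] * sz] + rng.normal(size=(n_units, sz)))
    X = np.hstack(cols)
    labels = np.repeat(np.arange(K), sizes)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    return df, labels


class TestFeatureCorrelations:
    def test_hand_computed_pearson(self):
        lsm = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]}, dtype=float)
        cm = feature_correlations(lsm)
        assert cm.r[0, 1] == pytest.approx(0.8)

    def test_identical_and_anticorrelated(self):
        x = np.arange(5.0)
        lsm = pd.DataFrame({"a": x, "b": x, "c": -x})
        cm = feature_correlations(lsm)
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert cm.r[0, 2] == pytest.approx(-1.0)

    def test_constant_feature_dropped(self):
        lsm = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5], "c": [3.0, 1, 2]})
        with pytest.warns(UserWarning, match="constant"):
            cm = feature_correlations(lsm)
        assert cm.feature_ids == ["a", "c"]

    def test_pairwise_complete_counts(self):
        lsm = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, np.nan, 3],
                            "c": [1.0, 4, 2, 2]})
        cm = feature_correlations(lsm)
        n = pd.DataFrame(cm.n_units, index=cm.feature_ids, columns=cm.feature_ids)
        assert n.loc["a", "b"] == 3 and n.loc["a", "c"] == 4


class TestFilterByFactor:
    def test_identity_and_empty(self):
        feats = ["a", "b", "c"]
        crit = {"a": 0.5, "b": 0.001, "c": 0.9}
        assert filter_by_factor(feats, crit, 1.0) == feats
        with pytest.warns(UserWarning, match="no features"):
            assert filter_by_factor(feats, crit, 0.0) == []

    def test_exact_count_matches_enumeration(self):
        rng = np.random.default_rng(9)
        p = pd.Series(rng.uniform(size=500), index=[f"f{i}" for i in range(500)])
        kept = filter_by_factor(p.index.tolist(), p, 0.01)
        assert len(kept) == int((p < 0.01).sum())

    def test_q_rule_inclusive(self):
        crit = {"a": 0.05, "b": 0.051}
        assert filter_by_factor(["a", "b"], crit, 0.05, rule="q") == ["a"]


class TestMMC:
    def test_two_perfect_blocks(self):
        cm, truth = block_corr_matrix([3, 3], within=1.0, between=0.0)
        part = mmc(cm)
        assert adjusted_rand_score(truth, part.labels()) == 1.0
        assert part.module_stats["size"].tolist() == [3, 3]

    def test_identity_matrix_single_module(self):
        cm, _ = block_corr_matrix([6], within=0.0, between=0.0)
        with pytest.warns(UserWarning, match="zero"):
            part = mmc(cm)
        assert part.assignment.nunique() == 1
        assert part.modularity_Q == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_brute_force(self):
        cm, _ = block_corr_matrix([5, 5, 5], within=0.8, between=0.1,
                                  jitter=0.05, seed=3)
        part = mmc(cm, sharpness_grid=[1, 2, 4])
        W = np.abs(cm.r) ** part.chosen_sharpness
        np.fill_diagonal(W, 0.0)
        labels = part.labels()
        assert part.modularity_Q == pytest.approx(
            brute_force_q(W, labels), rel=1e-10, abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(12)
        df, truth = sample_module_data(rng, 50, [10, 10, 10], share=0.7)
        cm = feature_correlations(df)
        part1 = mmc(cm)
        perm = rng.permutation(len(df.columns))
        ids = [cm.feature_ids[i] for i in perm]
        cm_p = CorrelationMatrix(ids, cm.r[np.ix_(perm, perm)])
        part2 = mmc(cm_p)
        a1 = part1.assignment[ids]
        a2 = part2.assignment[ids]
        assert adjusted_rand_score(a1, a2) == 1.0

    def test_repeat_runs_identical(self):
        rng = np.random.default_rng(13)
        df, _ = sample_module_data(rng, 40, [8, 8, 8], share=0.6)
        cm = feature_correlations(df)
        p1, p2 = mmc(cm), mmc(cm)
        assert p1.assignment.equals(p2.assignment)
        assert p1.chosen_sharpness == p2.chosen_sharpness

    def test_sharpening_used_and_helps(self):
        # noisy between-module correlation 0.3: the chosen s should exceed 1
        # and be no worse than s = 1 for recovery, in most seeds
        wins = 0
        sharpened = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            df, truth = sample_module_data(rng, 60, [25, 25, 25, 25],
                                           share=0.7, between_rho=0.3)
            cm = feature_correlations(df)
            part = mmc(cm)
            part1 = mmc(cm, sharpness_grid=[1])
            ari = adjusted_rand_score(truth, part.labels())
            ari1 = adjusted_rand_score(truth, part1.labels())
            if part.chosen_sharpness > 1:
                sharpened += 1
            if ari >= ari1 - 1e-12:
                wins += 1
        assert sharpened >= 15
        assert wins >= 15

    def test_too_few_features_rejected(self):
        cm, _ = block_corr_matrix([3], within=0.5, between=0.0)
        with pytest.raises(ValueError, match="at least 4"):
            mmc(cm)

    def test_logistic_transform_available(self):
        cm, truth = block_corr_matrix([4, 4], within=0.9, between=0.05)
        part = mmc(cm, sharpness_grid=[0.05, 0.1], transform="logistic")
        assert adjusted_rand_score(truth, part.labels()) == 1.0


class TestModuleOrderingAndFilter:
    @staticmethod
    def _partition(sizes, avgs):
        stats = pd.DataFrame({"size": sizes, "avg_abs_corr": avgs})
        stats = stats.sort_values("avg_abs_corr", ascending=False).reset_index(drop=True)
        stats.index = pd.RangeIndex(1, len(stats) + 1, name="module")
        stats["original_index"] = stats.index
        stats["excluded"] = False
        assignment = pd.Series(
            np.repeat(stats.index, stats["size"]),
            index=[f"f{i}" for i in range(int(stats['size'].sum()))])
        return ModulePartition(assignment=assignment, chosen_sharpness=1.0,
                               modularity_Q=0.5, module_stats=stats)

    def test_first_module_most_coherent(self, main_dataset):
        from gxd import ls_means
        spec, fm, meta, ph, truth = main_dataset
        lsm = ls_means(fm, meta, "line_diet")
        members = truth.features.index[truth.features["module"] > 0].tolist()
        part = mmc(feature_correlations(lsm, members))
        avgs = part.module_stats["avg_abs_corr"]
        assert avgs.loc[1] == avgs.max()
        assert (avgs.diff().dropna() <= 1e-12).all()  # descending order

    def test_size_and_coherence_filter(self):
        part = self._partition([23, 15, 25, 16, 20, 22, 9],
                               [0.61, 0.58, 0.54, 0.53, 0.52, 0.50001, 0.7])
        out = order_and_filter_modules(part, min_size=15, min_avg_corr=0.5)
        assert (~out.module_stats["excluded"]).sum() == 6
        excluded = out.module_stats[out.module_stats["excluded"]]
        assert excluded["size"].tolist() == [9]

    def test_identity_filter(self):
        part = self._partition([5, 3], [0.9, 0.2])
        out = order_and_filter_modules(part, min_size=1, min_avg_corr=0.0)
        assert not out.module_stats["excluded"].any()

    def test_all_excluded_warns(self):
        part = self._partition([2, 2], [0.1, 0.2])
        with pytest.warns(UserWarning, match="below"):
            out = order_and_filter_modules(part, min_size=15, min_avg_corr=0.5)
        assert out.retained_modules() == []
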