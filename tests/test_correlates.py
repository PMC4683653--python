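import itertools

import numpy as np
import pandas as pd
import pytest

from gxd import (
    CorrelationProfile,
    PhenotypeTable,
    forward_stepwise_bic,
    gross_trait_correlations,
    ls_means,
    trait_correlations,
    venn_overlap,
)


def _profile(trait, p_by_feature, diet="pooled"):
    tab = pd.DataFrame({"p": pd.Series(p_by_feature)})
    tab["r"] = 0.5
    tab["NLP"] = -np.log10(tab["p"])
    tab["n"] = 10
    return CorrelationProfile(trait=trait, diet=diet, table=tab)


class TestTraitCorrelations:
    def test_feature_equal_to_trait(self):
        units = pd.RangeIndex(6)
        feats = pd.DataFrame({"f1": np.arange(6.0)}, index=units)
        traits = pd.DataFrame({"weight": np.arange(6.0)}, index=units)
        prof = trait_correlations(feats, traits)["weight"]
        assert prof.table.loc["f1", "r"] == pytest.approx(1.0)

    def test_hand_pearson_with_exact_p(self):
        # r = 0.8 at n = 4: t = 0.8*sqrt(2)/0.6, p = 0.2 exactly (R pt oracle)
        feats = pd.DataFrame({"f1": [1.0, 2, 3, 4]})
        traits = pd.DataFrame({"weight": [1.0, 3, 2, 4]})
        tab = trait_correlations(feats, traits)["weight"].table
        assert tab.loc["f1", "r"] == pytest.approx(0.8)
        assert tab.loc["f1", "p"] == pytest.approx(0.2, rel=1e-10)

    def test_pooled_scope_n80_on_main_design(self, main_dataset):
        _, fm, meta, ph, _ = main_dataset
        lsm = ls_means(fm, meta, "line_diet")
        tl = ls_means(ph, meta, "line_diet")
        prof = trait_correlations(lsm.iloc[:, :20], tl)["weight"]
        assert (prof.table["n"] == 80).all()

    def test_diet_scope_restricts_units(self, main_dataset):
        _, fm, meta, ph, _ = main_dataset
        lsm = ls_means(fm, meta, "line_diet")
        tl = ls_means(ph, meta, "line_diet")
        prof = trait_correlations(lsm.iloc[:, :5], tl, scope="high_fat")["weight"]
        assert (prof.table["n"] == 20).all()
        assert prof.diet == "high_fat"

    def test_constant_feature_flagged(self):
        feats = pd.DataFrame({"f1": [1.0, 1, 1, 1], "f2": [1.0, 2, 3, 4]})
        traits = pd.DataFrame({"weight": [1.0, 3, 2, 4]})
        tab = trait_correlations(feats, traits)["weight"].table
        assert np.isnan(tab.loc["f1", "r"])
        assert not np.isnan(tab.loc["f2", "r"])

    def test_conserved_scenario_signs_agree_across_diets(self):
        from gxd import generate_dataset, preset_scenario
        spec = preset_scenario("conserved", seed=21)
        fm, meta, ph, truth = generate_dataset(spec)
        lsm = ls_means(fm, meta, "line_diet")
        tl = ls_means(ph, meta, "line_diet")
        members = truth.module_members(1)  # drives weight on both diets
        profs = [trait_correlations(lsm[members], tl, scope=d)["weight"]
                 for d in meta.diets]
        signs = np.sign(profs[0].table["r"]) == np.sign(profs[1].table["r"])
        assert signs.mean() >= 0.95


class TestGrossTraitCorrelations:
    def test_duplicated_trait_perfect(self):
        ph = PhenotypeTable(pd.DataFrame(
            {"weight": [1.0, 2, 3, 4], "triglyceride": [1.0, 2, 3, 4],
             "sugar": [4.0, 1, 3, 2]},
            index=pd.Index(list("abcd"), name="unit_id")))
        out = gross_trait_correlations(ph).set_index(["trait_1", "trait_2"])
        assert out.loc[("weight", "triglyceride"), "r"] == pytest.approx(1.0)

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(10)
        ph = PhenotypeTable(pd.DataFrame(
            rng.normal(size=(200, 3)), columns=["weight", "triglyceride", "sugar"],
            index=pd.Index([f"u{i}" for i in range(200)], name="unit_id")))
        out = gross_trait_correlations(ph)
        assert (out["r"].abs() < 0.14).all()

    def test_missing_unit_changes_count(self, tiny_dataset):
        _, _, ph = tiny_dataset  # weight has one missing value
        out = gross_trait_correlations(ph).set_index(["trait_1", "trait_2"])
        assert out.loc[("weight", "triglyceride"), "n"] == 3
        assert out.loc[("triglyceride", "sugar"), "n"] == 4


class TestVennOverlap:
    def test_spec_example_subsets(self):
        profiles = [
            _profile("A", {"f1": 0.001, "f2": 0.001, "f3": 0.5}),
            _profile("B", {"f1": 0.5, "f2": 0.001, "f3": 0.5}),
            _profile("C", {"f1": 0.5, "f2": 0.5, "f3": 0.5}),
            _profile("D", {"f1": 0.5, "f2": 0.5, "f3": 0.5}),
        ]
        out = venn_overlap(profiles, 0.01)
        assert out.exactly(1) == 1 and out.exactly(2) == 1
        assert out.exactly(3) == 0 and out.exactly(4) == 0

    def test_zero_threshold_empty(self):
        profiles = [_profile("A", {"f1": 0.001}), _profile("B", {"f1": 0.5})]
        assert venn_overlap(profiles, 0.0).total() == 0

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(11)
        feats = [f"f{i}" for i in range(300)]
        profiles = [_profile(t, dict(zip(feats, rng.uniform(size=300))))
                    for t in "ABC"]
        out = venn_overlap(profiles, 0.2)
        sig = {p.trait: p.significant(0.2) for p in profiles}
        for subset in (frozenset(s) for r in range(1, 4)
                       for s in itertools.combinations("ABC", r)):
            labels = frozenset(f"{t}:pooled" for t in subset)
            expect = len(set.intersection(*(sig[t] for t in subset))
                         - set.union(*(sig[t] for t in set("ABC") - subset))
                         if subset != frozenset("ABC")
                         else set.intersection(*(sig[t] for t in subset)))
            assert out.subset_counts.get(labels, 0) == expect
        assert out.total() == len(set.union(*sig.values()))

    def test_mismatched_universe_rejected(self):
        profiles = [_profile("A", {"f1": 0.1}), _profile("B", {"f2": 0.1})]
        with pytest.raises(ValueError, match="universe"):
            venn_overlap(profiles, 0.05)


class TestForwardStepwiseBIC:
    def test_noiseless_identity(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(50, 10)),
                         columns=[f"x{i}" for i in range(10)])
        y = 2.0 * X["x3"]
        res = forward_stepwise_bic(X, y, trait="weight")
        assert res.selected == ["x3"]
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficients["x3"] == pytest.approx(2.0)

    def test_r2_matches_independent_residual_computation(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"x{i}" for i in range(8)])
        y = X["x0"] - 0.5 * X["x5"] + rng.normal(0, 0.5, 60)
        res = forward_stepwise_bic(X, y)
        Xs = np.column_stack([np.ones(60)] + [X[f].to_numpy() for f in res.selected])
        beta, *_ = np.linalg.lstsq(Xs, y.to_numpy(), rcond=None)
        rss = np.sum((y.to_numpy() - Xs @ beta) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert res.r_squared == pytest.approx(1 - rss / tss, rel=1e-10)

    def test_bic_trace_strictly_decreasing(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(80, 20)), columns=[f"x{i:02d}" for i in range(20)])
        y = 0.8 * X["x01"] + 0.8 * X["x07"] + rng.normal(0, 0.5, 80)
        res = forward_stepwise_bic(X, y)
        assert len(res.selected) >= 2
        assert (np.diff(res.bic_trace) < 0).all()

    def test_collinear_candidate_skipped(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        X["dup"] = X["a"]
        y = X["a"] + rng.normal(0, 0.1, 40)
        with pytest.warns(UserWarning, match="collinear"):
            res = forward_stepwise_bic(X, y)
        assert "a" in res.selected and "dup" not in res.selected

    def test_prefilter_restricts_candidates(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(size=(80, 30)), columns=[f"x{i:02d}" for i in range(30)])
        y = 1.0 * X["x00"] + rng.normal(0, 0.5, 80)
        res = forward_stepwise_bic(X, y, prefilter_p=0.01)
        assert "marginal p < 0.01" in res.candidate_definition
        assert "x00" in res.selected
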