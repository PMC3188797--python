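"""Interaction models, mixture splits, four-group analysis, joint MI."""

import numpy as np
import pandas as pd
import pytest

from chromexpress import (
    all_pairs_table,
    fit_interaction_model,
    fit_pairwise_model,
    fit_singleton_model,
    four_group_expression,
    gmm_split,
    normalized_joint_mi,
)


def _xy(seed, n, m):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, m)), columns=[f"x{j}" for j in range(m)],
        index=[f"t{i}" for i in range(n)],
    )
    return rng, X


class TestInteractionModel:
    @pytest.mark.parametrize("m", [2, 5, 12, 16])
    def test_pair_term_count(self, m):
        rng, X = _xy(0, 400, m)
        y = pd.Series(rng.normal(size=400), index=X.index)
        res = fit_interaction_model(X, y, cv_seed=None)
        assert len(res.pair_terms) == m * (m - 1) // 2

    def test_additive_null_rarely_flags_interactions(self):
        hits = 0
        for seed in range(100):
            rng, X = _xy(seed, 1000, 2)
            y = X["x0"] + X["x1"] + pd.Series(rng.normal(scale=0.1, size=1000), index=X.index)
            res = fit_interaction_model(X, y, cv_seed=None)
            hits += bool(res.significant_pairs)
        assert hits <= 5  # alpha=0.001, 1 term, 100 runs

    def test_multiplicative_signal_detected(self):
        rng, X = _xy(7, 500, 2)
        y = X["x0"] * X["x1"] + pd.Series(rng.normal(scale=0.1, size=500), index=X.index)
        res = fit_interaction_model(X, y, cv_seed=None)
        assert ("x0", "x1") in res.significant_pairs
        assert res.p_values["x0:x1"] < 1e-10

    def test_rank_deficiency_names_collinear_terms(self):
        rng, X = _xy(1, 200, 2)
        X["x1"] = X["x0"]
        y = pd.Series(rng.normal(size=200), index=X.index)
        with pytest.raises(ValueError, match="collinear"):
            fit_interaction_model(X, y, cv_seed=None)

    def test_needs_more_rows_than_terms(self):
        rng, X = _xy(2, 60, 12)  # 1 + 12 + 66 = 79 terms > 60 rows
        y = pd.Series(rng.normal(size=60), index=X.index)
        with pytest.raises(ValueError, match="need n >"):
            fit_interaction_model(X, y)

    def test_singleton_matches_interaction_on_additive_data(self):
        rng, X = _xy(3, 800, 4)
        y = X @ np.array([1.0, 0.5, -0.5, 0.8]) + rng.normal(scale=0.5, size=800)
        y = pd.Series(y, index=X.index)
        inter = fit_interaction_model(X, y, cv_seed=5, cv_repeats=10)
        single = fit_singleton_model(X, y, cv_seed=5, cv_repeats=10)
        assert inter.cv_pcc == pytest.approx(single.cv_pcc, abs=0.02)

    def test_interaction_model_wins_on_multiplicative_data(self):
        rng, X = _xy(4, 800, 3)
        y = X["x0"] + 2.0 * X["x1"] * X["x2"] + pd.Series(
            rng.normal(scale=0.3, size=800), index=X.index
        )
        inter = fit_interaction_model(X, y, cv_seed=5, cv_repeats=10)
        single = fit_singleton_model(X, y, cv_seed=5, cv_repeats=10)
        assert inter.cv_pcc > single.cv_pcc + 0.1

    def test_uninformative_predictors_give_near_zero_cv_pcc(self):
        rng, X = _xy(5, 600, 3)
        y = pd.Series(rng.normal(size=600), index=X.index)
        single = fit_singleton_model(X, y, cv_seed=2, cv_repeats=10)
        assert abs(single.cv_pcc) < 0.15


class TestPairwiseModel:
    def test_identical_features_rejected(self):
        rng, X = _xy(0, 300, 1)
        y = pd.Series(rng.normal(size=300), index=X.index)
        with pytest.raises(ValueError, match="collinear"):
            fit_pairwise_model(X["x0"], X["x0"].rename("x0b"), y)

    def test_null_interaction_with_informative_mains(self):
        main_hits, inter_hits = 0, 0
        for seed in range(100):
            rng, X = _xy(seed + 100, 400, 2)
            y = X["x0"] + X["x1"] + pd.Series(rng.normal(scale=0.5, size=400), index=X.index)
            res = fit_pairwise_model(X["x0"], X["x1"], y)
            main_hits += (res.p_values["x0"] < 0.001) and (res.p_values["x1"] < 0.001)
            inter_hits += bool(res.significant_pairs)
        assert main_hits == 100
        assert inter_hits <= 5

    def test_all_pairs_enumerated_once(self):
        rng, X = _xy(9, 300, 5)
        y = pd.Series(rng.normal(size=300), index=X.index)
        table = all_pairs_table(X, y)
        assert len(table) == 10
        pairs = set(map(tuple, table[["feature_i", "feature_j"]].to_numpy()))
        assert len(pairs) == 10


class TestGmmSplit:
    def test_well_separated_mixture_recovered(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, size=1000).astype(bool)
        x = pd.Series(np.where(truth, rng.normal(6.0, 1.0, 1000), rng.normal(0.0, 1.0, 1000)))
        split = gmm_split(x, seed=1)
        assert split.method == "mixture"
        err = np.mean((split.labels == "H") != truth)
        assert min(err, 1 - err) < 0.01
        assert split.means == pytest.approx([0.0, 6.0], abs=0.2)
        assert split.weights.sum() == pytest.approx(1.0)

    def test_unimodal_falls_back_to_median(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=501))
        split = gmm_split(x, seed=0)
        assert split.method == "median"
        counts = split.labels.value_counts()
        assert abs(counts["H"] - counts["L"]) <= 1

    def test_affine_rescaling_leaves_labels_unchanged(self):
        rng = np.random.default_rng(3)
        x = pd.Series(np.r_[rng.normal(0, 1, 300), rng.normal(5, 1, 300)])
        s1 = gmm_split(x, seed=4)
        s2 = gmm_split(x * 13.0 + 7.0, seed=4)
        assert (s1.labels == s2.labels).all()
        assert s1.method == s2.method

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 50"):
            gmm_split(pd.Series(np.arange(10.0)))


class TestFourGroups:
    def _labels(self, arr):
        return pd.Series(np.where(arr, "H", "L"), index=[f"t{i}" for i in range(len(arr))])

    def test_two_activators_order(self):
        rng = np.random.default_rng(5)
        n = 2000
        a = rng.random(n) < 0.5
        b = rng.random(n) < 0.5
        y = pd.Series(2.0 * a + 2.0 * b + rng.normal(scale=0.7, size=n),
                      index=[f"t{i}" for i in range(n)])
        res = four_group_expression(self._labels(a), self._labels(b), y)
        means = res.group_stats["mean"]
        assert means["LL"] < means["HL"] < means["HH"]
        assert means["LL"] < means["LH"] < means["HH"]
        assert means["HL"] == pytest.approx(means["LH"], abs=0.2)

    def test_activator_plus_repressor(self):
        rng = np.random.default_rng(6)
        n = 2000
        act = rng.random(n) < 0.5
        rep = rng.random(n) < 0.5
        y = pd.Series(2.0 * act - 2.0 * rep + rng.normal(scale=0.7, size=n),
                      index=[f"t{i}" for i in range(n)])
        # first mark = repressor, second = activator: repressor-H/activator-L lowest
        res = four_group_expression(self._labels(rep), self._labels(act), y)
        means = res.group_stats["mean"]
        assert means.idxmin() == "HL"
        assert means.idxmax() == "LH"

    def test_null_labels_rarely_significant(self):
        flagged = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 200
            a = self._labels(rng.random(n) < 0.5)
            b = self._labels(rng.random(n) < 0.5)
            y = pd.Series(rng.normal(size=n), index=a.index)
            res = four_group_expression(a, b, y)
            flagged += bool((res.tests["p_holm"].dropna() < 0.05).any())
        assert flagged <= 10

    def test_six_comparisons_reported(self):
        rng = np.random.default_rng(7)
        a = self._labels(rng.random(300) < 0.5)
        b = self._labels(rng.random(300) < 0.5)
        y = pd.Series(rng.normal(size=300), index=a.index)
        res = four_group_expression(a, b, y)
        assert len(res.tests) == 6
        assert (res.tests["p_holm"].dropna() >= res.tests["p_raw"].dropna() - 1e-12).all()


class TestNormalizedJointMI:
    def test_duplicated_feature_gives_ratio_one(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=500)
        e = h + rng.normal(scale=0.5, size=500)
        assert normalized_joint_mi(e, h, h) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_ratio_at_least_one_where_defined(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=300)
        h1 = e + rng.normal(scale=2.0, size=300)
        h2 = rng.normal(size=300)
        ratio = normalized_joint_mi(e, h1, h2)
        assert np.isnan(ratio) or ratio >= 1.0

    def test_xor_structure_gives_large_ratio(self):
        rng = np.random.default_rng(11)
        n = 4000
        h1 = rng.normal(size=n)
        h2 = rng.normal(size=n)
        e = np.where((h1 > 0) ^ (h2 > 0), 1.0, 0.0) + rng.normal(scale=0.05, size=n)
        ratio = normalized_joint_mi(e, h1, h2, k_bins=2)
        assert ratio > 5.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 100"):
            normalized_joint_mi(np.arange(10.0), np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError, match="k_bins"):
            normalized_joint_mi(np.arange(200.0), np.arange(200.0), np.arange(200.0), k_bins=1)
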