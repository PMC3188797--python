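"""Classification/regression models, ROC/AUC, cross-validation, designs."""

import numpy as np
import pandas as pd
import pytest

from chromexpress import (
    ExpressionModel,
    ExpressionTable,
    LabeledDesign,
    TranscriptAnnotation,
    SignalTrack,
    bin_design,
    coverage_feature,
    cross_validate,
    discretize_expression,
    evaluate_pcc,
    multibin_design,
    roc_auc,
    subset_design,
    train_classifier,
    variance_explained,
)
from chromexpress.config import DEFAULT_SUBSETS


def _design(X: np.ndarray, y: np.ndarray) -> LabeledDesign:
    idx = [f"t{i}" for i in range(len(y))]
    Xdf = pd.DataFrame(X, index=idx, columns=[f"x{j}" for j in range(X.shape[1])])
    yv = pd.Series(y, index=idx)
    return LabeledDesign(Xdf, yv, discretize_expression(yv))


class TestDiscretize:
    def test_median_split(self):
        out = discretize_expression(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(out) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        out = discretize_expression(pd.Series([5.0, 5.0, 5.0, 9.0]))
        assert list(out) == ["low", "low", "low", "high"]

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            discretize_expression(pd.Series([2.0, 2.0, 2.0]))

    def test_near_balance(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=101))
        out = discretize_expression(y)
        assert abs((out == "high").sum() - (out == "low").sum()) <= 1


class TestRocAuc:
    def test_pair_counting_example(self):
        # 3 of the 4 (pos, neg) pairs are correctly ordered
        scores = [0.9, 0.8, 0.7, 0.85]
        labels = ["high", "high", "low", "low"]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_perfect_and_all_tied(self):
        assert roc_auc([3, 2, 1, 0], ["high", "high", "low", "low"])[1] == 1.0
        assert roc_auc([1, 1, 1, 1], ["high", "high", "low", "low"])[1] == 0.5

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = np.where(rng.random(n) < 0.4, "high", "low")
        if len(set(labels)) < 2:
            labels[0] = "high"
            labels[1] = "low"
        _, auc = roc_auc(scores, labels)
        pos = scores[labels == "high"]
        neg = scores[labels == "low"]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_negated_scores_complement(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.5, "high", "low")
        a1 = roc_auc(scores, labels)[1]
        a2 = roc_auc(-scores, labels)[1]
        assert a1 + a2 == pytest.approx(1.0)

    def test_roc_points_are_monotone(self):
        rng = np.random.default_rng(4)
        pts, _ = roc_auc(rng.normal(size=60), np.where(rng.random(60) < 0.5, "high", "low"))
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], ["high", "high"])


class TestCrossValidation:
    def test_same_seed_reproduces_per_repeat_vector(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(120, 3))
        y = X @ [1.0, -1.0, 0.5] + rng.normal(scale=0.5, size=120)
        d = _design(X, y)
        r1 = cross_validate(d, "svm", n_repeats=5, seed=42)
        r2 = cross_validate(d, "svm", n_repeats=5, seed=42)
        np.testing.assert_array_equal(r1.per_repeat, r2.per_repeat)
        assert r1.mean == pytest.approx(np.mean(r1.per_repeat))
        assert r1.sd == pytest.approx(np.std(r1.per_repeat, ddof=1))

    def test_separable_data_trains_to_auc_one(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(30), np.ones(30) * 10.0]
        X = np.column_stack([y + rng.normal(scale=0.1, size=60), rng.normal(size=60)])
        d = _design(X, y)
        res = train_classifier(d)
        _, auc = roc_auc(res.decision_scores(d.X), d.y_class)
        assert auc == 1.0

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = np.arange(40.0)
        d = _design(X, y)
        forced = LabeledDesign(d.X, d.y_value, pd.Series("low", index=d.X.index))
        with pytest.raises(ValueError, match="single class"):
            ExpressionModel(forced, kind="svm").fit()

    def test_noiseless_linear_svr_pcc_near_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        y = X @ [2.0, -1.0, 0.5]
        rep = cross_validate(_design(X, y), "svr", n_repeats=5, seed=0, kernel="linear")
        assert rep.mean > 0.99

    def test_linear_svr_matches_ols_in_linear_setting(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 4))
        y = X @ [1.0, 0.5, -0.5, 0.2] + rng.normal(scale=1.0, size=400)
        d = _design(X, y)
        svr = cross_validate(d, "svr", n_repeats=10, seed=1, kernel="linear", C=10.0)
        ols = cross_validate(d, "ols", n_repeats=10, seed=1)
        assert variance_explained(svr.mean) == pytest.approx(
            variance_explained(ols.mean), abs=0.02
        )

    def test_noise_monotonically_degrades_performance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(500, 4))
        signal = X @ [1.0, 1.0, -1.0, 0.5]
        aucs, pccs = [], []
        for sd in (0.5, 2.0, 8.0):
            y = signal + rng.normal(scale=sd, size=500)
            d = _design(X, y)
            aucs.append(cross_validate(d, "svm", n_repeats=10, seed=7).mean)
            pccs.append(cross_validate(d, "svr", n_repeats=10, seed=7).mean)
        assert aucs[0] > aucs[1] > aucs[2]
        assert pccs[0] > pccs[1] > pccs[2]


class TestVarianceExplained:
    def test_square_identity(self):
        assert variance_explained(0.75) == pytest.approx(0.5625)
        assert variance_explained(0.0) == 0.0
        assert variance_explained(1.0) == 1.0
        assert variance_explained(-0.6) == pytest.approx(0.36)

    def test_pcc_edge_cases(self):
        assert evaluate_pcc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert evaluate_pcc([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
        assert np.isnan(evaluate_pcc([1, 1, 1], [1, 2, 3]))


class TestDesigns:
    def test_bin_and_subset_columns(self, medium_ds):
        d = bin_design(medium_ds.tensor, medium_ds.expression, "EEMB", "TSS:d1")
        assert d.X.shape[1] == 16
        his = subset_design(d, DEFAULT_SUBSETS["HIS"])
        assert his.X.shape[1] == 10
        k79 = subset_design(d, DEFAULT_SUBSETS["K79"])
        assert k79.X.shape[1] == 3
        # named subsets partition ALL together with the unnamed leftovers
        union = set(DEFAULT_SUBSETS["H3"]) | set(DEFAULT_SUBSETS["HIS"]) | set(
            DEFAULT_SUBSETS["XIF"]) | set(DEFAULT_SUBSETS["POLII"])
        assert union == set(d.X.columns)

    def test_multibin_concatenation(self, medium_ds):
        d = multibin_design(medium_ds.tensor, medium_ds.expression, "EEMB")
        assert d.X.shape[1] == 16 * 40
        single = bin_design(medium_ds.tensor, medium_ds.expression, "EEMB", "TSS:d1")
        cols = {f"{c}@TSS:d1" for c in single.X.columns}
        assert cols <= set(d.X.columns)

    def test_informative_subset_beats_decoy(self, medium_ds):
        d = bin_design(medium_ds.tensor, medium_ds.expression, "EEMB", "TSS:d1")
        k79 = cross_validate(subset_design(d, DEFAULT_SUBSETS["K79"]), "svm", n_repeats=10, seed=13)
        decoy = cross_validate(subset_design(d, DEFAULT_SUBSETS["XIF"]), "svm", n_repeats=10, seed=13)
        assert k79.mean > decoy.mean + 0.2

    def test_multibin_at_least_matches_best_single_bin(self, medium_ds):
        d40 = multibin_design(medium_ds.tensor, medium_ds.expression, "EEMB")
        multi = cross_validate(d40, "svm", n_repeats=5, seed=21)
        best_single = max(
            cross_validate(
                bin_design(medium_ds.tensor, medium_ds.expression, "EEMB", lbl),
                "svm", n_repeats=5, seed=21,
            ).mean
            for lbl in ("TSS:u1", "TSS:d1", "TSS:d2")
        )
        assert multi.mean >= best_single - 0.02


class TestCoverage:
    def _track_for(self, t, strong_bins, weak_bins, width=100):
        probes = []
        for i in range(t.length // width):
            lo = t.start + i * width
            val = 10.0 if i in strong_bins else 0.1
            if i in weak_bins:
                val = 0.1
            probes.append((t.chrom, lo, lo + width, val))
        return SignalTrack("f", "s", "probe", probes)

    def test_crafted_fractions(self):
        t = TranscriptAnnotation("t", "g", "chrI", "+", 0, 1000)  # 10 body bins
        track = self._track_for(t, strong_bins={0, 4, 7}, weak_bins=set())
        frac = coverage_feature([t], [track], quantile=0.5)
        assert frac.loc["t", "f"] == pytest.approx(0.3)

    def test_extremes(self):
        t = TranscriptAnnotation("t", "g", "chrI", "+", 0, 1000)
        t2 = TranscriptAnnotation("t2", "g2", "chrI", "+", 5000, 6000)
        probes = [("chrI", i * 100, (i + 1) * 100, 5.0) for i in range(10)]
        probes += [("chrI", 5000 + i * 100, 5100 + i * 100, 1.0) for i in range(10)]
        track = SignalTrack("f", "s", "probe", probes)
        frac = coverage_feature([t, t2], [track], quantile=0.5)
        assert frac.loc["t", "f"] == 1.0  # all bins above the pooled median
        assert frac.loc["t2", "f"] == 0.0

    def test_short_transcript_masked(self):
        t = TranscriptAnnotation("s", "g", "chrI", "+", 0, 50)
        t2 = TranscriptAnnotation("t", "g2", "chrI", "+", 1000, 2000)
        probes = [("chrI", 1000 + i * 100, 1100 + i * 100, float(i)) for i in range(10)]
        frac = coverage_feature([t, t2], [SignalTrack("f", "s", "probe", probes)])
        assert np.isnan(frac.loc["s", "f"])
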