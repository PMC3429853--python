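import numpy as np
import pandas as pd
import pytest

from mirscan.features import FeatureVector, build_feature_vector, feature_frame
from mirscan.model import (RankDeficiencyError, TermResolutionError,
                           bin_by_feature, builtin_table2, correlate_features,
                           cross_validate, fit_ols, r2_methods, reduce_model,
                           roc_auc, score, select_parameters)
from mirscan.synth import SynthSpec, synth_activity_frame

from conftest import random_guide
from oracles import pair_counting_auc


def zero_vector(extra=()):
    terms = dict.fromkeys(builtin_table2().terms, 0.0)
    terms.update(extra)
    return FeatureVector(None, terms)


class TestScore:
    def test_intercept_on_zero_vector(self):
        assert score(zero_vector(), builtin_table2()) == -43.85

    def test_a20_vs_c20_difference(self):
        a = zero_vector({"A_20": 1.0})
        c = zero_vector({"C_20": 1.0})
        t2 = builtin_table2()
        # C_20 is not a model term; add it as a zero-weight resolvable column
        diff = t2.score(a) - t2.score(c)
        assert diff == pytest.approx(-1.067)

    def test_cubic_term_arithmetic(self):
        fv = zero_vector({"dG": -30.0, "dG2": 900.0, "dG3": -27000.0})
        expected = (-43.85 + (-2.694) * (-30) + (-0.06917) * 900
                    + (-0.0005959) * (-27000))
        assert score(fv, builtin_table2()) == pytest.approx(expected)

    def test_table2_contents(self):
        t2 = builtin_table2()
        assert len(t2.terms) == 41  # 4 thermodynamic + 37 nucleotide terms
        assert t2.terms["U_1"] == 1.989
        assert t2.terms["dG"] == -2.694
        assert t2.terms["dG2"] == -0.06917
        assert t2.terms["dG3"] == -0.0005959
        assert t2.terms["dG1"] == 0.3705
        nuc = [t for t in t2.terms if "_" in t and t[0] in "ACGU"]
        assert len(nuc) == 37

    def test_unresolvable_term_errors(self):
        fv = FeatureVector(None, {"dG": -30.0})
        with pytest.raises(TermResolutionError):
            builtin_table2().score(fv)

    def test_linear_in_thermo_features(self):
        t2 = builtin_table2()
        base = t2.score(zero_vector())
        x1 = t2.score(zero_vector({"dG1": 1.0})) - base
        x3 = t2.score(zero_vector({"dG1": 3.0})) - base
        assert x3 == pytest.approx(3 * x1)

    def test_score_frame_matches_scalar(self, rng):
        guides = [random_guide(rng) for _ in range(20)]
        frame = feature_frame(guides)
        vec = builtin_table2().score_frame(frame)
        for k, g in enumerate(guides):
            assert vec[k] == pytest.approx(builtin_table2().score(build_feature_vector(g)))


class TestCorrelateFeatures:
    def test_perfect_correlation(self, rng):
        y = rng.normal(size=100)
        X = pd.DataFrame({"same": y, "anti": -y})
        out = correlate_features(X, y)
        assert out.loc["same", "R"] == pytest.approx(1.0)
        assert out.loc["anti", "R"] == pytest.approx(-1.0)

    def test_constant_column_degenerate(self, rng):
        y = rng.normal(size=50)
        out = correlate_features(pd.DataFrame({"const": np.ones(50)}), y)
        assert out.loc["const", "R"] == 0.0
        assert out.loc["const", "p"] == 1.0
        assert out.loc["const", "degenerate"]

    def test_null_p_uniformity(self, rng):
        # permuted feature: p-values roughly uniform over repeated draws
        pvals = []
        y = rng.normal(size=200)
        for _ in range(200):
            x = rng.permutation(y)
            out = correlate_features(pd.DataFrame({"x": x}), y)
            pvals.append(out.loc["x", "p"])
        assert 0.3 < np.mean(pvals) < 0.7
        assert np.mean(np.array(pvals) < 0.05) < 0.15

    def test_requires_varying_activity(self):
        with pytest.raises(ValueError):
            correlate_features(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), np.ones(3))


class TestSelectParameters:
    def test_planted_feature_kept_noise_rejected(self, rng):
        n = 2000
        signal = rng.normal(size=n)
        y = signal + rng.normal(scale=np.sqrt(1 / 0.5**2 - 1), size=n)
        X = pd.DataFrame({"signal": signal, "noise": rng.normal(size=n)})
        rep = select_parameters(X, y, n_repeats=50, seed=0)
        assert "signal" in rep.kept
        assert "noise" not in rep.kept

    def test_trivial_thresholds_keep_everything(self, rng):
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = rng.normal(size=n)
        rep = select_parameters(X, y, r_min=0.0, p_max=1.01,
                                s_max=float("inf"), n_repeats=10, seed=0)
        assert rep.kept == list("abcd")

    def test_too_small_dataset(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        with pytest.raises(ValueError):
            select_parameters(X, rng.normal(size=10), n_splits=5)

    def test_stability_flags_heterogeneous_feature(self, rng):
        # a feature correlated only in half the data has high S_n
        n = 1000
        x = rng.normal(size=n)
        y = np.where(np.arange(n) < n // 2, x, -x) + rng.normal(scale=0.3, size=n)
        X = pd.DataFrame({"unstable": x})
        rep = select_parameters(X, y, n_repeats=30, seed=1, s_max=0.065)
        assert rep.table.loc["unstable", "S_n"] > 0.065
        assert "unstable" not in rep.kept


class TestFitOLS:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 10, 50)
        fit = fit_ols(pd.DataFrame({"x": x}), 2 * x + 1)
        assert fit.table.terms["x"] == pytest.approx(2.0)
        assert fit.table.intercept == pytest.approx(1.0)
        assert fit.train_r == pytest.approx(1.0)

    def test_noncv_r2_identity(self, rng):
        # in-sample predictions: the Methods R^2 equals squared Pearson R
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + 0.5 * rng.normal(size=n)
        fit = fit_ols(X, y)
        preds = fit.predict(X)
        r = np.corrcoef(preds, y)[0, 1]
        assert r2_methods(y, preds) == pytest.approx(r ** 2)
        assert fit.train_r == pytest.approx(r)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(RankDeficiencyError) as err:
            fit_ols(X, rng.normal(size=50))
        assert any(c in ("x", "x2") for c in err.value.columns)

    def test_more_columns_than_rows(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 6)))
        X.columns = [f"c{i}" for i in range(6)]
        with pytest.raises(ValueError):
            fit_ols(X, rng.normal(size=4))

    def test_pvalues_in_unit_interval(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        fit = fit_ols(X, rng.normal(size=100))
        assert all(0.0 <= p <= 1.0 for p in fit.pvalues.values())


class TestReduceModel:
    def _planted(self, rng, n=800):
        X = pd.DataFrame({
            "A_1": rng.integers(0, 2, n).astype(float),
            "C_1": rng.integers(0, 2, n).astype(float),
            "G_1": rng.integers(0, 2, n).astype(float),
            "dG": rng.normal(size=n),
        })
        y = 2.0 * X["A_1"].to_numpy() + X["dG"].to_numpy() + rng.normal(scale=0.5, size=n)
        return X, y

    def test_all_significant_unchanged(self, rng):
        n = 500
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = X["a"].to_numpy() + X["b"].to_numpy() + 0.1 * rng.normal(size=n)
        fit = reduce_model(X, y)
        assert set(fit.table.terms) == {"a", "b"}

    def test_irrelevant_indicators_removed_relevant_kept(self, rng):
        X, y = self._planted(rng)
        fit = reduce_model(X, y)
        assert "A_1" in fit.table.terms
        assert "dG" in fit.table.terms
        assert "C_1" not in fit.table.terms
        assert "G_1" not in fit.table.terms

    def test_at_most_one_indicator_per_position_per_round(self, rng):
        X, y = self._planted(rng)
        one_round = reduce_model(X, y, max_rounds=1)
        junk_left = {"C_1", "G_1"} & set(one_round.table.terms)
        assert len(junk_left) == 1  # only one of the two same-position terms dropped


class TestCrossValidate:
    def test_noiseless_linear(self, rng):
        n = 200
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = 3 * X["x"].to_numpy() - 1
        cv = cross_validate(X, y, n=5, seed=0)
        assert cv.r2 == pytest.approx(1.0, abs=1e-9)

    def test_mean_predictor_r2_zero(self, rng):
        y = rng.normal(size=100)
        assert r2_methods(y, np.full(100, y.mean())) == pytest.approx(0.0)

    def test_folds_partition(self, rng):
        n = 103
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.normal(size=n)
        cv = cross_validate(X, y, n=5, seed=3)
        sizes = np.bincount(cv.fold_assignment)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
        assert len(sizes) == 5

    def test_seed_changes_folds_not_counts(self, rng):
        n = 60
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = X["x"].to_numpy() + rng.normal(size=n)
        cv1 = cross_validate(X, y, n=5, seed=1)
        cv2 = cross_validate(X, y, n=5, seed=2)
        assert not np.array_equal(cv1.fold_assignment, cv2.fold_assignment)
        assert np.bincount(cv2.fold_assignment).sum() == n

    def test_too_many_folds(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=3)})
        with pytest.raises(ValueError):
            cross_validate(X, rng.normal(size=3), n=5)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_auc([1, 2, 3, 10, 11, 12], [10, 20, 30, 80, 90, 95], 75)
        assert roc.auc == pytest.approx(1.0)

    def test_random_predictions_near_half(self, rng):
        n = 4000
        preds = rng.normal(size=n)
        acts = rng.uniform(0, 100, size=n)
        roc = roc_auc(preds, acts, 75)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            preds = np.round(rng.normal(size=n), 1)  # induce ties
            acts = rng.uniform(0, 100, size=n)
            if not (np.any(acts >= 75) and np.any(acts < 75)):
                continue
            roc = roc_auc(preds, acts, 75)
            assert roc.auc == pytest.approx(
                pair_counting_auc(preds, acts >= 75))

    def test_curve_monotone(self, rng):
        preds = rng.normal(size=500)
        acts = rng.uniform(0, 100, size=500)
        roc = roc_auc(preds, acts, 50)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [10, 20, 30], 75)


class TestBinByFeature:
    def test_single_bin_global_mean(self, rng):
        x = rng.uniform(0, 1, 100)
        y = rng.uniform(0, 100, 100)
        out = bin_by_feature(x, y, [-0.1, 1.1])
        assert out["count"].iloc[0] == 100
        assert out["mean_activity"].iloc[0] == pytest.approx(y.mean())

    def test_edge_values_go_left(self):
        out = bin_by_feature([1.0, 2.0, 2.0], [10, 20, 30], [0.0, 2.0, 4.0])
        assert list(out["count"]) == [3, 0]
        assert np.isnan(out["mean_activity"].iloc[1])

    def test_planted_bell_shape(self, rng):
        x = rng.uniform(-50, -20, 5000)
        y = 100 * np.exp(-((x + 33) ** 2) / 20) + rng.normal(scale=1, size=5000)
        edges = np.arange(-50, -19, 3)
        out = bin_by_feature(x, y, edges)
        best = out.loc[out["mean_activity"].idxmax()]
        assert best["bin_left"] <= -33 <= best["bin_right"] + 3

    def test_bad_edges(self):
        with pytest.raises(ValueError):
            bin_by_feature([1.0], [1.0], [0.0, 0.0, 1.0])


class TestParameterRecoverySmall:
    """Scaled-down recovery check; the full 20-seed run lives in acceptance."""

    def test_recovery_two_seeds(self):
        t2 = builtin_table2()
        cols = list(t2.terms)
        for seed in (0, 1):
            df = synth_activity_frame(SynthSpec(n=3000, seed=seed, noise_sd=1.0))
            X = feature_frame(list(df["guide_seq"]), columns=cols)
            fit = fit_ols(X, df["latent_ln"].to_numpy())
            for term, truth in t2.terms.items():
                est, se = fit.table.terms[term], fit.stderr[term]
                assert abs(est - truth) < 4 * se, term
            assert abs(fit.table.intercept - t2.intercept) < 4 * fit.stderr["intercept"]
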