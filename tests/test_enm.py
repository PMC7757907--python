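import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from zonarisk.enm import (
    FeatureSpec,
    auc,
    build_features,
    fit_maxent,
    fit_scaling,
    jackknife,
    percent_contribution,
    predict_logistic,
    sample_background,
    split_presences,
    threshold_10pct,
)
from zonarisk.occurrences import OccurrenceSet
from zonarisk.raster import PredictorStack, RasterGrid


class TestBackgroundSampling:
    def test_clamps_to_available_valid_cells(self, flat_grid):
        r = flat_grid(np.ones((5, 4)))
        mask = np.ones((5, 4), dtype=bool)  # True = nodata
        mask[0, :3] = False
        mask[3, 2] = False
        mask[4, 0] = False
        stack = PredictorStack({"a": RasterGrid(values=r.values, transform=r.transform, mask=mask)})
        bg = sample_background(stack, n=10_000, seed=0)
        assert len(bg) == 5

    def test_same_seed_identical(self, small_stack):
        a = sample_background(small_stack, n=50, seed=4)
        b = sample_background(small_stack, n=50, seed=4)
        assert a.equals(b)

    def test_draws_are_uniform_over_cells(self, flat_grid):
        stack = PredictorStack({"a": flat_grid(np.arange(20, dtype=float).reshape(5, 4))})
        counts = np.zeros(20)
        for rep in range(400):
            bg = sample_background(stack, n=5, seed=rep)
            idx = (bg["a"].to_numpy()).astype(int)
            np.add.at(counts, idx, 1)
        assert chisquare(counts).pvalue > 1e-3


class TestFeatures:
    def spec_01(self, knots=4):
        return FeatureSpec(hinge_knots=knots).with_scaling(["x"], [0.0], [1.0])

    def test_all_features_zero_at_origin_except_reverse_hinges(self):
        F, owners, names = build_features(np.array([[0.0]]), self.spec_01())
        by = dict(zip(names, F[0]))
        assert by["x:linear"] == 0 and by["x:quadratic"] == 0
        assert all(v == 0 for n, v in by.items() if "hinge_fwd" in n)
        assert all(v == 1 for n, v in by.items() if "hinge_rev" in n)

    def test_all_features_saturate_at_one(self):
        F, _, names = build_features(np.array([[1.0]]), self.spec_01())
        by = dict(zip(names, F[0]))
        assert by["x:linear"] == 1 and by["x:quadratic"] == 1
        assert all(v == 1 for n, v in by.items() if "hinge_fwd" in n)
        assert all(v == 0 for n, v in by.items() if "hinge_rev" in n)

    def test_hand_evaluated_forward_hinge(self):
        spec = FeatureSpec(hinge_knots=1).with_scaling(["x"], [0.0], [1.0])
        F, _, names = build_features(np.array([[0.75]]), spec)
        by = dict(zip(names, F[0]))
        assert by["x:hinge_fwd@0.500"] == pytest.approx(0.5)  # (0.75-0.5)/(1-0.5)
        assert by["x:hinge_rev@0.500"] == 0.0

    def test_all_feature_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-5, 5, size=(100, 3))
        spec = fit_scaling(X, ["a", "b", "c"], FeatureSpec())
        F, _, _ = build_features(X, spec)
        assert F.min() >= 0 and F.max() <= 1

    def test_constant_variable_dropped_with_warning(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        spec = fit_scaling(X, ["a", "const"], FeatureSpec(classes=("linear",)))
        with pytest.warns(UserWarning, match="constant"):
            F, owners, names = build_features(X, spec)
        assert names == ["a:linear"]


class TestSplit:
    def test_paperlike_sizes(self):
        df = pd.DataFrame({"id": [f"r{i}" for i in range(74)], "lon": np.arange(74.0),
                           "lat": np.zeros(74), "status": "native", "source": "x"})
        occ = OccurrenceSet(records=df)
        train, test = split_presences(occ, train_frac=0.75, seed=0)
        assert (len(train), len(test)) == (56, 18)  # round(0.75 * 74) = 56

    def test_partition_is_disjoint_and_complete(self):
        df = pd.DataFrame({"id": [f"r{i}" for i in range(21)], "lon": np.arange(21.0),
                           "lat": np.zeros(21), "status": "invaded", "source": "x"})
        occ = OccurrenceSet(records=df)
        train, test = split_presences(occ, seed=3)
        ids = set(train.records["id"]) | set(test.records["id"])
        assert len(ids) == 21
        assert not set(train.records["id"]) & set(test.records["id"])

    def test_same_seed_same_partition(self):
        df = pd.DataFrame({"id": [f"r{i}" for i in range(10)], "lon": np.arange(10.0),
                           "lat": np.zeros(10), "status": "invaded", "source": "x"})
        occ = OccurrenceSet(records=df)
        a1, b1 = split_presences(occ, seed=7)
        a2, b2 = split_presences(occ, seed=7)
        assert a1.records.equals(a2.records) and b1.records.equals(b2.records)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_pure_ties_give_half(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_three_of_four_concordant_pairs(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        sp = rng.normal(1, 1, size=40)
        sb = rng.normal(0, 1, size=200)
        y = np.concatenate([np.ones(40), np.zeros(200)])
        expect = roc_auc_score(y, np.concatenate([sp, sb]))
        assert auc(sp, sb) == pytest.approx(expect, abs=1e-12)


def fit_1d(presence_x, background_x, **kw):
    spec = kw.pop("spec", FeatureSpec(classes=("linear",)))
    return fit_maxent(np.asarray(presence_x, float).reshape(-1, 1),
                      np.asarray(background_x, float).reshape(-1, 1),
                      spec, var_names=["x"], **kw)


class TestFit:
    def test_no_signal_gives_near_zero_coefficients(self):
        rng = np.random.default_rng(0)
        bg = rng.uniform(size=500)
        pres = bg[rng.choice(500, size=60, replace=False)]
        m = fit_1d(pres, bg)
        assert np.abs(m.lambdas).max() < 0.2
        q = np.exp(m.raw_scores(bg.reshape(-1, 1)) - m.log_z)
        assert q.max() / q.min() < 1.5  # near-uniform raw density

    def test_positive_effect_recovered_with_gridsearch_oracle(self):
        rng = np.random.default_rng(1)
        bg = rng.uniform(size=400)
        pres = rng.beta(6, 1.5, size=80)  # concentrated at high x
        m = fit_1d(pres, bg)
        lam = m.lambdas[0]
        assert lam > 0

        # brute-force 1-D penalized-objective scan over lambda
        spec = m.spec
        F_u, _, _ = build_features(np.concatenate([bg, pres]).reshape(-1, 1), spec)
        F_p, _, _ = build_features(pres.reshape(-1, 1), spec)
        grid = np.linspace(-10, 10, 4001)
        from scipy.special import logsumexp
        obj = [F_p.mean() * l - logsumexp(F_u[:, 0] * l) - m.betas[0] * abs(l) for l in grid]
        best = grid[int(np.argmax(obj))]
        assert np.sign(best) == np.sign(lam)
        assert lam == pytest.approx(best, abs=0.02)

    def test_huge_regularization_zeroes_everything(self):
        rng = np.random.default_rng(2)
        m = fit_1d(rng.beta(5, 1, 50), rng.uniform(size=300), reg_multiplier=1e4)
        assert np.all(m.lambdas == 0.0)

    def test_gibbs_density_normalized_over_universe(self, default_study):
        m = default_study["model"]
        assert m.n_universe == len(m.background_X) + m.n_presence
        universe = np.vstack([m.background_X, m.presence_X])
        q = m.raw_density(universe)
        assert q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_objective_nondecreasing_over_sweeps(self):
        rng = np.random.default_rng(3)
        m = fit_1d(rng.beta(4, 2, 60), rng.uniform(size=400), spec=FeatureSpec())
        assert np.all(np.diff(m.gain_trace) >= -1e-12)


class TestPredict:
    def test_uniform_model_predicts_half_everywhere(self, small_stack):
        rng = np.random.default_rng(4)
        bg = sample_background(small_stack, n=300, seed=1)
        X = bg[small_stack.names].to_numpy()
        pres = X[rng.choice(len(X), 40, replace=False)]
        m = fit_maxent(pres, X, FeatureSpec(), var_names=small_stack.names,
                       reg_multiplier=1e4)  # forces all-zero coefficients
        surface = predict_logistic(m, small_stack)
        assert np.allclose(surface.valid_values(), 0.5, atol=1e-12)

    def test_logistic_preserves_auc_of_raw_scores(self, default_study):
        m = default_study["model"]
        bg = m.background_X
        rng = np.random.default_rng(5)
        pres = bg[rng.choice(len(bg), 30, replace=False)] + 0.01
        raw_auc = auc(m.raw_scores(pres), m.raw_scores(bg))
        log_auc = auc(m.predict(pres), m.predict(bg))
        assert raw_auc == pytest.approx(log_auc, abs=1e-12)

    def test_surface_in_unit_interval(self, default_study):
        surf = default_study["surface"]
        v = surf.valid_values()
        assert v.min() > 0 and v.max() < 1


class TestImportance:
    def test_contributions_sum_to_hundred(self, default_study):
        c = percent_contribution(default_study["model"])
        assert c.sum() == pytest.approx(100.0, abs=1e-6)
        assert (c >= 0).all()

    def test_single_signal_variable_takes_all_credit(self):
        rng = np.random.default_rng(6)
        bg = np.column_stack([rng.uniform(size=400), rng.uniform(size=400)])
        pres = np.column_stack([rng.beta(6, 1, 70), rng.uniform(size=70)])
        m = fit_maxent(pres, bg, FeatureSpec(classes=("linear", "quadratic")),
                       var_names=["signal", "noise"])
        c = percent_contribution(m)
        assert c["signal"] > 85
        assert c.sum() == pytest.approx(100.0)

    def test_jackknife_counts_and_signal_attribution(self):
        rng = np.random.default_rng(7)
        bg = np.column_stack([rng.uniform(size=300), rng.uniform(size=300)])
        pres = np.column_stack([rng.beta(6, 1, 60), rng.uniform(size=60)])
        jk = jackknife(pres, bg, FeatureSpec(classes=("linear", "quadratic")),
                       var_names=["signal", "noise"])
        assert jk.shape == (2, 4)  # 2 variables x 2 sub-models x (gain, auc)
        # the signal variable alone carries nearly all the gain
        assert jk.loc["signal", "gain_only"] > 5 * max(jk.loc["noise", "gain_only"], 1e-9)
        # removing the irrelevant variable barely changes the gain
        assert jk.loc["noise", "gain_without"] == pytest.approx(
            jk.loc["signal", "gain_only"], rel=0.25)


class TestThreshold:
    def test_equal_predictions_return_that_value(self):
        rng = np.random.default_rng(8)
        bg = rng.uniform(size=300)
        m = fit_1d(rng.beta(5, 1, 40), bg, reg_multiplier=1e4)  # constant model
        thr = threshold_10pct(m, np.array([[0.3], [0.6], [0.9]]))
        assert thr == pytest.approx(0.5)

    def test_linear_interpolation_percentile(self):
        preds = np.arange(0.1, 1.01, 0.1)
        assert np.percentile(preds, 10, method="linear") == pytest.approx(0.19)

    def test_masking_zeroes_exactly_below_threshold_cells(self, default_study):
        from zonarisk.enm import apply_threshold

        surf = default_study["surface"]
        thr = 0.4
        masked = apply_threshold(surf, thr)
        below = surf.valid & (surf.values < thr)
        above = surf.valid & (surf.values >= thr)
        assert np.all(masked.values[below] == 0)
        assert np.array_equal(masked.values[above], surf.values[above])


class TestDiscrimination:
    def test_heldout_auc_in_high_accuracy_regime(self, default_study):
        """On the default strong-signal landscape the model discriminates
        held-out presences from background at AUC >= 0.9."""
        assert default_study["auc_test"] >= 0.9

    def test_predicted_surface_tracks_truth(self, default_study):
        assert default_study["spearman_truth"] >= 0.8
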