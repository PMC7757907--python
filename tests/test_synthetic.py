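import numpy as np
import pytest
from scipy.stats import chisquare

from zonarisk.synthetic import (
    SyntheticScenario,
    generate_host_raster,
    generate_predictor_stack,
    generate_true_suitability,
    perturb_scenario,
    sample_presences,
    write_fixture,
)
from zonarisk.raster import read_ascii_grid


class TestPredictorStackGeneration:
    def test_layer_count_matches_request(self):
        sc = SyntheticScenario(n_predictors=19,
                               collinear_pairs=(),
                               linear_coefficients=(0.0,) * 19,
                               quadratic_coefficients=(0.0,) * 19)
        assert len(generate_predictor_stack(sc)) == 19

    def test_collinear_pairs_hit_targets(self, small_scenario, small_stack):
        names = small_stack.names
        for i, j, target in small_scenario.collinear_pairs:
            a = small_stack[names[i]].values.ravel()
            b = small_stack[names[j]].values.ravel()
            r = np.corrcoef(a, b)[0, 1]
            assert abs(r - target) <= 0.05

    def test_same_seed_bit_identical(self, small_scenario):
        s1 = generate_predictor_stack(small_scenario)
        s2 = generate_predictor_stack(small_scenario)
        for name in s1.names:
            assert np.array_equal(s1[name].values, s2[name].values)

    def test_different_seed_differs(self, small_scenario, small_stack):
        import dataclasses
        other = generate_predictor_stack(dataclasses.replace(small_scenario, seed=43))
        assert not np.array_equal(other[other.names[0]].values,
                                  small_stack[small_stack.names[0]].values)

    def test_degenerate_grid_rejected(self):
        sc = SyntheticScenario(grid_shape=(3, 50), n_predictors=2, collinear_pairs=(),
                               linear_coefficients=(1.0, 0.0), quadratic_coefficients=(0.0, 0.0))
        with pytest.raises(ValueError, match="too small"):
            generate_predictor_stack(sc)

    def test_fields_are_spatially_smooth(self, small_stack):
        # neighbouring cells must correlate far more than distant ones
        v = small_stack[small_stack.names[0]].values
        lag1 = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert lag1 > 0.8


class TestTrueSuitability:
    def test_zero_coefficients_give_uniform_half(self, small_stack):
        n = len(small_stack)
        s = generate_true_suitability(small_stack, np.zeros(n), np.zeros(n))
        assert np.allclose(s.values, 0.5)

    def test_single_positive_coefficient_is_monotone(self, small_stack):
        n = len(small_stack)
        lin = np.zeros(n)
        lin[2] = 1.5
        s = generate_true_suitability(small_stack, lin, np.zeros(n))
        x = small_stack[small_stack.names[2]].values.ravel()
        order = np.argsort(x)
        assert np.all(np.diff(s.values.ravel()[order]) >= 0)

    def test_cell_matches_hand_computed_logistic(self, small_stack):
        n = len(small_stack)
        lin, quad = np.zeros(n), np.zeros(n)
        lin[0], quad[0] = 2.0, -1.0
        s = generate_true_suitability(small_stack, lin, quad, intercept=0.5)
        vals = small_stack[small_stack.names[0]].values
        z = (vals - vals.mean()) / vals.std()
        eta = 0.5 + 2.0 * z[7, 11] - 1.0 * z[7, 11] ** 2
        assert s.values[7, 11] == pytest.approx(1.0 / (1.0 + np.exp(-eta)), abs=1e-12)

    def test_mismatched_lengths_rejected(self, small_stack):
        with pytest.raises(ValueError, match="length"):
            generate_true_suitability(small_stack, np.zeros(3), np.zeros(3))

    def test_values_strictly_inside_unit_interval(self, small_truth):
        assert small_truth.values.min() > 0
        assert small_truth.values.max() < 1


class TestPresenceSampling:
    def test_forced_support_returns_those_cells(self, flat_grid):
        vals = np.zeros((5, 4))
        vals[0, 0] = vals[2, 3] = vals[4, 1] = 0.2
        occ = sample_presences(flat_grid(vals), n=3, seed=0)
        rows, cols = flat_grid.transform.index_of(occ.lon, occ.lat)
        assert sorted(zip(rows, cols)) == [(0, 0), (2, 3), (4, 1)]

    def test_sampled_cells_enriched_in_suitability(self, small_truth):
        occ = sample_presences(small_truth, n=100, seed=11)
        r, c = small_truth.transform.index_of(occ.lon, occ.lat)
        assert small_truth.values[r, c].mean() > 2 * small_truth.values.mean()

    def test_same_seed_identical(self, small_truth):
        a = sample_presences(small_truth, n=20, seed=5)
        b = sample_presences(small_truth, n=20, seed=5)
        assert a.records.equals(b.records)

    def test_all_zero_suitability_rejected(self, flat_grid):
        with pytest.raises(ValueError, match="zero"):
            sample_presences(flat_grid(np.zeros((5, 4))), n=2, seed=0)

    def test_oversampling_rejected(self, flat_grid):
        with pytest.raises(ValueError, match="cannot sample"):
            sample_presences(flat_grid(np.ones((5, 4))), n=21, seed=0)

    def test_empirical_density_tracks_suitability(self):
        """Coarse-bin chi-square: presence counts follow the true surface."""
        sc = SyntheticScenario(grid_shape=(50, 50), n_predictors=4, collinear_pairs=(),
                               linear_coefficients=(2.0, -1.5, 0.0, 0.0),
                               quadratic_coefficients=(0.0, 0.0, 0.0, 0.0),
                               intercept=-1.0, presence_n=60, seed=3)
        truth = generate_true_suitability(generate_predictor_stack(sc),
                                          sc.linear_coefficients,
                                          sc.quadratic_coefficients,
                                          intercept=sc.intercept)
        n = 250
        occ = sample_presences(truth, n=n, seed=21)
        r, c = truth.transform.index_of(occ.lon, occ.lat)
        counts = np.zeros((5, 5))
        np.add.at(counts, (r // 10, c // 10), 1)
        expected = np.add.reduceat(np.add.reduceat(truth.values, np.arange(0, 50, 10), 0),
                                   np.arange(0, 50, 10), 1)
        expected = n * expected / expected.sum()
        keep = expected.ravel() > 1
        stat = chisquare(counts.ravel()[keep], expected.ravel()[keep] *
                         counts.ravel()[keep].sum() / expected.ravel()[keep].sum())
        assert stat.pvalue > 1e-3


class TestHostRaster:
    def test_minimum_is_zero_and_nonnegative(self, small_scenario):
        host = generate_host_raster(small_scenario)
        assert host.values.min() == 0.0
        assert np.all(host.values >= 0)
        assert host.units == "ha"

    def test_same_seed_identical(self, small_scenario):
        a = generate_host_raster(small_scenario)
        b = generate_host_raster(small_scenario)
        assert np.array_equal(a.values, b.values)


class TestPerturbation:
    def test_identity_perturbation(self, small_stack):
        out = perturb_scenario(small_stack, temp_offset=0.0, precip_scale=1.0)
        for name in small_stack.names:
            assert np.array_equal(out[name].values, small_stack[name].values)

    def test_temperature_offset_shifts_means(self, small_stack):
        out = perturb_scenario(small_stack, temp_offset=2.0)
        for name in small_stack.names:
            layer = small_stack[name]
            if layer.units == "°C":
                assert out[name].values.mean() - layer.values.mean() == pytest.approx(2.0)

    def test_precipitation_scaled(self):
        sc = SyntheticScenario(n_predictors=12)  # bio12 is precipitation-like
        stack = generate_predictor_stack(sc)
        out = perturb_scenario(stack, precip_scale=0.8)
        assert stack["bio12"].units == "mm"
        assert out["bio12"].values.sum() == pytest.approx(0.8 * stack["bio12"].values.sum())

    def test_negative_precip_scale_rejected(self, small_stack):
        with pytest.raises(ValueError, match="precip_scale"):
            perturb_scenario(small_stack, precip_scale=-0.5)


def test_fixture_bundle_roundtrip(tmp_path, small_scenario):
    paths = write_fixture(small_scenario, tmp_path / "fx")
    truth = read_ascii_grid(paths["true_suitability"])
    assert truth.transform == small_scenario.transform
    back = SyntheticScenario.from_yaml(paths["scenario"])
    assert back == small_scenario
    assert (paths["predictors"] / "bio01.asc").exists()
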