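import numpy as np
import pytest

from invadeloss import (
    FactorLayer,
    GeoDetector,
    GridSpec,
    Raster,
    classify_interaction,
    discretize_factor,
    factor_q,
    interaction_q,
)
from invadeloss.errors import ConfigError, StatisticError
from invadeloss.geodetector import categorical_factor


def brute_force_q(values, strata):
    """Oracle: explicit grouping with two-pass population variances."""
    values = np.asarray(values, dtype=float).ravel()
    strata = np.asarray(strata).ravel()
    n = len(values)
    var = np.mean((values - values.mean()) ** 2)
    acc = 0.0
    for h in np.unique(strata):
        grp = values[strata == h]
        acc += len(grp) * np.mean((grp - grp.mean()) ** 2)
    return 1.0 - acc / (n * var)


def layer(grid, strata):
    strata = np.asarray(strata, dtype=np.int64)
    return FactorLayer(strata, int(strata.max()))


class TestFactorQ:
    def test_perfect_stratification_gives_one(self):
        g = GridSpec(10, 10, 1000.0)
        strata = (np.arange(100).reshape(g.shape) % 4) + 1
        outcome = Raster(g, strata.astype(float))  # constant per stratum
        res = factor_q(outcome, layer(g, strata))
        assert res.q == pytest.approx(1.0, abs=1e-15)

    def test_single_stratum_gives_zero(self, rng):
        g = GridSpec(10, 10, 1000.0)
        outcome = Raster(g, rng.standard_normal(g.shape))
        res = factor_q(outcome, layer(g, np.ones(g.shape, dtype=int)))
        assert res.q == pytest.approx(0.0, abs=1e-15)

    def test_worked_example_point_eight(self):
        g = GridSpec(1, 4, 1000.0)
        outcome = Raster(g, [[1.0, 2.0, 3.0, 4.0]])
        res = factor_q(outcome, layer(g, [[1, 1, 2, 2]]))
        # 1 - (2*0.25 + 2*0.25) / (4*1.25)
        assert res.q == pytest.approx(0.8, abs=1e-15)
        assert res.stratum_sizes == {1: 2, 2: 2}

    def test_constant_outcome_undefined(self):
        g = GridSpec(2, 2, 1000.0)
        with pytest.raises(StatisticError):
            factor_q(Raster(g, np.ones(g.shape)),
                     layer(g, np.ones(g.shape, dtype=int)))

    def test_matches_brute_force_oracle(self, rng):
        g = GridSpec(20, 20, 1000.0)
        for _ in range(50):
            vals = rng.standard_normal(g.shape)
            strata = rng.integers(1, rng.integers(2, 9), g.shape)
            q = factor_q(Raster(g, vals), layer(g, strata)).q
            assert q == pytest.approx(brute_force_q(vals, strata),
                                      abs=1e-12)
            assert -1e-12 <= q <= 1 + 1e-12

    def test_refinement_never_decreases_q(self, rng):
        g = GridSpec(15, 15, 1000.0)
        vals = rng.standard_normal(g.shape)
        strata = rng.integers(1, 4, g.shape)
        q0 = factor_q(Raster(g, vals), layer(g, strata)).q
        # split stratum 1 randomly into 1 and 4
        refined = strata.copy()
        split = (strata == 1) & (rng.random(g.shape) < 0.5)
        refined[split] = 4
        q1 = factor_q(Raster(g, vals), layer(g, refined)).q
        assert q1 >= q0 - 1e-12

    def test_affine_invariance(self, rng):
        g = GridSpec(12, 12, 1000.0)
        vals = rng.standard_normal(g.shape)
        strata = rng.integers(1, 5, g.shape)
        q0 = factor_q(Raster(g, vals), layer(g, strata)).q
        q1 = factor_q(Raster(g, 3.7 * vals - 11.0), layer(g, strata)).q
        assert q1 == pytest.approx(q0, abs=1e-12)

    def test_nodata_cells_excluded(self, rng):
        g = GridSpec(5, 5, 1000.0)
        vals = rng.standard_normal(g.shape)
        strata = rng.integers(1, 3, g.shape)
        masked = vals.copy()
        masked[0, :] = -9999.0
        q_masked = factor_q(Raster(g, masked), layer(g, strata)).q
        assert q_masked == pytest.approx(
            brute_force_q(vals[1:], strata[1:]), abs=1e-12)


class TestInteractionQ:
    def test_self_interaction_collapses(self, rng):
        g = GridSpec(10, 10, 1000.0)
        vals = rng.standard_normal(g.shape)
        f = layer(g, rng.integers(1, 4, g.shape))
        out = Raster(g, vals)
        assert interaction_q(out, f, f) == pytest.approx(
            factor_q(out, f).q, abs=1e-12)

    def test_constant_second_factor_collapses(self, rng):
        g = GridSpec(10, 10, 1000.0)
        vals = rng.standard_normal(g.shape)
        f1 = layer(g, rng.integers(1, 4, g.shape))
        f2 = layer(g, np.ones(g.shape, dtype=int))
        out = Raster(g, vals)
        assert interaction_q(out, f1, f2) == pytest.approx(
            factor_q(out, f1).q, abs=1e-12)

    def test_fully_separating_pair_gives_one(self):
        g = GridSpec(2, 2, 1000.0)
        out = Raster(g, [[1.0, 2.0], [3.0, 4.0]])
        f1 = layer(g, [[1, 1], [2, 2]])
        f2 = layer(g, [[1, 2], [1, 2]])
        assert interaction_q(out, f1, f2) == pytest.approx(1.0, abs=1e-15)


class TestClassifyInteraction:
    @pytest.mark.parametrize("q1,q2,q12,expected", [
        (0.3, 0.4, 0.7, "independent"),
        (0.3, 0.4, 0.9, "nonlinear_enhancement"),
        (0.3, 0.4, 0.35, "single_factor_nonlinear_weakening"),
        (0.3, 0.4, 0.5, "bifactor_enhancement"),
        (0.3, 0.4, 0.1, "nonlinear_weakening"),
    ])
    def test_printed_rules(self, q1, q2, q12, expected):
        assert classify_interaction(q1, q2, q12) == expected

    def test_equality_tolerance(self):
        assert classify_interaction(0.3, 0.4, 0.7 + 5e-10) == "independent"

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            classify_interaction(1.2, 0.3, 0.5)


class TestDiscretize:
    def test_quantile_equal_stratum_sizes(self):
        g = GridSpec(10, 10, 1000.0)
        r = Raster(g, np.arange(1.0, 101.0).reshape(g.shape))
        fl = discretize_factor(r, 5, "quantile")
        counts = np.bincount(fl.strata.ravel())[1:]
        np.testing.assert_array_equal(counts, 20)

    def test_equal_interval_split_at_midpoint(self):
        g = GridSpec(1, 11, 1000.0)
        r = Raster(g, [np.linspace(0.0, 10.0, 11)])
        fl = discretize_factor(r, 2, "equal_interval")
        assert (fl.strata[0, :5] == 1).all()
        assert (fl.strata[0, 6:] == 2).all()

    def test_constant_raster_rejected(self):
        g = GridSpec(3, 3, 1000.0)
        with pytest.raises(StatisticError):
            discretize_factor(Raster(g, np.ones(g.shape)), 3)

    def test_categorical_passthrough_preserves_partition(self, rng):
        g = GridSpec(6, 6, 1000.0)
        from conftest import make_label_raster
        lab = make_label_raster(g, rng.integers(3, 9, g.shape))
        fl = categorical_factor(lab, "cat")
        # same partition: cells share a stratum iff they share a label
        for s in np.unique(fl.strata):
            labs = np.unique(lab.labels[fl.strata == s])
            assert len(labs) == 1

    def test_natural_breaks_orders_strata(self, rng):
        g = GridSpec(10, 10, 1000.0)
        r = Raster(g, rng.random(g.shape))
        fl = discretize_factor(r, 4, "natural_breaks")
        assert fl.n_levels == 4
        means = [r.values[fl.strata == s].mean() for s in range(1, 5)]
        assert means == sorted(means)


class TestGeoDetectorEstimator:
    def test_fit_ranks_factors_and_classifies_pairs(self, rng):
        g = GridSpec(20, 20, 1000.0)
        driver = rng.standard_normal(g.shape)
        outcome = Raster(g, 2.0 * driver + 0.1 * rng.standard_normal(g.shape))
        noise = Raster(g, rng.standard_normal(g.shape))
        det = GeoDetector(n_classes=5).fit(
            {"driver": Raster(g, driver), "noise": noise}, outcome)
        assert det.q_.index[0] == "driver"
        assert det.q_["driver"] > det.q_["noise"]
        assert len(det.interactions_) == 1
        assert det.interactions_["category"].iloc[0] in (
            "bifactor_enhancement", "nonlinear_enhancement", "independent")

    def test_get_params_roundtrip(self):
        det = GeoDetector(n_classes=7, method="equal_interval")
        assert det.get_params()["n_classes"] == 7
        det.set_params(n_classes=3)
        assert det.n_classes == 3


class TestClassificationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(q1=st.floats(0, 1), q2=st.floats(0, 1), q12=st.floats(0, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_exactly_one_category_always_assigned(self, q1, q2, q12):
        assert classify_interaction(q1, q2, q12) in {
            "nonlinear_weakening", "single_factor_nonlinear_weakening",
            "bifactor_enhancement", "independent", "nonlinear_enhancement"}
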