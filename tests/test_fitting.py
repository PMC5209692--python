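import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiopbpk import (FixtureSpec, default_config, fit,
                        make_heart_series, make_plasma_series,
                        two_stage_protocol, weighted_residuals)
from cardiopbpk.fitting import (FittingError, ObservedSeries,
                                apply_parameters, weighted_least_squares)


def series_from(times, values, variable="venous_plasma", errors=None):
    recs = [(t, v, variable, 1.0 if errors is None else errors[i])
            for i, (t, v) in enumerate(zip(times, values))]
    return ObservedSeries.from_records(recs)


class TestWeightedResiduals:
    def test_perfect_fit_gives_zero(self):
        obs = series_from([1, 2, 3], [0.1, 0.2, 0.3])
        assert np.all(weighted_residuals([0.1, 0.2, 0.3], obs) == 0.0)

    def test_direct_formula_and_ssr(self):
        obs = series_from([1.0], [1.0])
        assert weighted_residuals([2.0], obs) == pytest.approx([1.0])
        res = np.array([1.0, -2.0, 3.0])
        assert float(np.sum(res ** 2)) == 14.0

    def test_error_weighting(self):
        obs = series_from([1.0], [1.0], errors=[0.5])
        assert weighted_residuals([2.0], obs) == pytest.approx([2.0])

    def test_length_mismatch_rejected(self):
        obs = series_from([1, 2], [0.1, 0.2])
        with pytest.raises(FittingError):
            weighted_residuals([0.1], obs)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.floats(0.01, 10.0), st.floats(0.01, 10.0)),
                    min_size=1, max_size=8))
    def test_antisymmetry_under_swapping_model_and_observed(self, pairs):
        mod = np.array([p[0] for p in pairs])
        obs_vals = [p[1] for p in pairs]
        times = np.arange(1.0, len(pairs) + 1)
        forward = weighted_residuals(mod, series_from(times, obs_vals))
        backward = weighted_residuals(np.array(obs_vals),
                                      series_from(times, mod))
        assert forward == pytest.approx(-backward, rel=1e-12)


class TestObservedSeries:
    def test_schema_validation(self):
        with pytest.raises(FittingError, match="unknown observed"):
            series_from([1.0], [1.0], variable="aorta")
        with pytest.raises(FittingError, match="nonnegative"):
            series_from([-1.0], [1.0])

    def test_csv_round_trip(self, tmp_path):
        obs = series_from([0.5, 3.5], [0.1, 0.2], variable="total_heart")
        path = tmp_path / "obs.csv"
        obs.to_csv(path, header_comment="synthetic test data")
        again = ObservedSeries.read_csv(path)
        assert np.allclose(again.data["value"], obs.data["value"])
        assert again.data["variable"].tolist() == ["total_heart"] * 2


class TestLeastSquaresCore:
    def test_linear_model_matches_closed_form(self):
        """A straight line through the origin has the analytic solution
        a = sum(t*y)/sum(t*t); the optimizer must land on it."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.9])
        obs = series_from(t, y)

        def predict(values):
            return values["a"] * t

        res = weighted_least_squares(predict, {"a": 0.3}, obs)
        a_hat = float(np.sum(t * y) / np.sum(t * t))
        assert res.estimates["a"] == pytest.approx(a_hat, rel=1e-6)
        assert res.converged
        # frozen from the closed form: SE^2 = SSR/(n-1) / sum(t^2)
        ssr = float(np.sum((a_hat * t - y) ** 2))
        se = np.sqrt(ssr / 3.0 / float(np.sum(t * t)))
        assert res.standard_errors["a"] == pytest.approx(se, rel=1e-4)

    def test_zero_free_parameters_rejected(self):
        obs = series_from([1.0], [1.0])
        with pytest.raises(FittingError):
            weighted_least_squares(lambda v: np.array([1.0]), {}, obs)

    def test_unknown_parameter_rejected(self):
        obs = series_from([1.0], [1.0])
        with pytest.raises(FittingError, match="unknown fittable"):
            fit({"body_weight": 70.0}, default_config(), obs)


class TestModelFitting:
    def test_noiseless_recovery_from_perturbed_starts(self, default_cfg):
        truth = {"k_a": 0.8, "Kp_re": 52.6, "Q_pf": 0.01, "P": 0.40}
        spec = FixtureSpec(cv=0.0, true_parameters=truth)
        plasma = make_plasma_series(spec)
        res = fit({"k_a": 1.2, "Kp_re": 30.0}, default_cfg, plasma,
                  fixed={"Q_pf": 0.01, "P": 0.40})
        assert res.converged
        for name, true_val in (("k_a", 0.8), ("Kp_re", 52.6)):
            assert res.estimates[name] == pytest.approx(true_val, rel=1e-3)
        assert all(se >= 0 for se in res.standard_errors.values())
        assert len(res.residuals) == len(plasma)

    def test_observation_beyond_simulated_span_rejected(self, default_cfg):
        obs = series_from([100.0], [0.01])
        with pytest.raises(FittingError, match="outside the simulated"):
            fit({"k_a": 0.8}, default_cfg, obs)

    def test_two_stage_noiseless_ssr_near_zero(self, default_cfg):
        truth = {"k_a": 0.8, "Kp_re": 52.6, "Q_pf": 0.012, "P": 0.78}
        spec = FixtureSpec(cv=0.0, true_parameters=truth,
                           pin_anchor=False, heart_scale=1.0)
        s1, s2 = two_stage_protocol(make_plasma_series(spec),
                                    make_heart_series(spec), default_cfg)
        assert s1.ssr < 1e-6
        assert s2.ssr < 1e-6
        assert s1.names == ("k_a", "Kp_re")
        assert s2.names == ("Q_pf", "P")

    def test_plasma_only_input_fails_stage_two(self, default_cfg):
        spec = FixtureSpec(cv=0.0)
        plasma = make_plasma_series(spec)
        with pytest.raises(FittingError, match="total_heart"):
            two_stage_protocol(plasma, plasma, default_cfg)

    def test_absorption_bias_shrinks_with_noise(self, default_cfg):
        """Stage-1 recovery error of k_a decreases as the observation
        noise is reduced (fixed seed per level)."""
        errors = {}
        for cv in (0.0, 0.2):
            spec = FixtureSpec(cv=cv, seed=5,
                               true_parameters={"k_a": 0.8, "Kp_re": 52.6,
                                                "Q_pf": 0.01, "P": 0.40})
            res = fit({"k_a": 1.0, "Kp_re": 30.0}, default_cfg,
                      make_plasma_series(spec),
                      fixed={"Q_pf": 0.01, "P": 0.40})
            errors[cv] = abs(res.estimates["k_a"] - 0.8) / 0.8
        assert errors[0.0] < 1e-3
        assert errors[0.0] < errors[0.2]


def test_apply_parameters_round_trip(default_cfg):
    cfg = apply_parameters(default_cfg, {"k_a": 1.5, "Q_pf": 0.02})
    assert cfg.drug.k_a == 1.5
    assert cfg.heart.Q_pf == 0.02
    assert default_cfg.drug.k_a == 0.80075  # original untouched
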