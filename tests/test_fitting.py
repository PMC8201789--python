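"""WLS fitting: weights, starting values, recovery, oracle agreement."""

import numpy as np
import pytest
from sklearn.base import clone

from critspeed import (
    CriticalSpeedRegressor,
    ModelFamily,
    Params,
    SyntheticConfig,
    TrialSet,
    fit_battery,
    fit_trialset,
    initial_params,
    observation_weights,
    predict_time,
    sample_cohort,
)
from ._oracles import grid_search_two_param, ols_slope_intercept
from .conftest import exact_trials

TWO, THREE, EXP = ModelFamily.TWO_PARAM, ModelFamily.THREE_PARAM, ModelFamily.THREE_PARAM_EXP


class TestObservationWeights:
    def test_inverse_proportional_normalised(self):
        w = observation_weights([100.0, 200.0, 400.0])
        assert w == pytest.approx([12 / 7, 6 / 7, 3 / 7])
        assert w.sum() == pytest.approx(3.0)

    def test_constant_reduces_to_ols(self):
        assert observation_weights([7.0, 7.0, 7.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            observation_weights([100.0, 0.0, 400.0])

    def test_scale_free(self):
        y = np.array([88.0, 356.0, 900.0])
        assert observation_weights(60.0 * y) == pytest.approx(observation_weights(y))


class TestInitialParams:
    def test_exact_for_two_param_data(self, two_param_exact):
        start = initial_params(two_param_exact, TWO)
        assert start.cs == pytest.approx(4.0, abs=1e-9)
        assert start.d_prime == pytest.approx(200.0, abs=1e-6)

    def test_group_mean_start_matches_ols_oracle(self, group_trials):
        slope, intercept = ols_slope_intercept(group_trials.times, group_trials.distances)
        start = initial_params(group_trials, TWO)
        assert start.cs == pytest.approx(slope, rel=1e-9)
        assert start.d_prime == pytest.approx(intercept, rel=1e-9)
        assert 4.2 < start.cs < 4.7

    def test_smax_start_rule(self, group_trials):
        assert initial_params(group_trials, THREE).s_max == pytest.approx(1.5 * 6.192)
        start = initial_params(group_trials, EXP)
        assert start.s_max == pytest.approx(1.4 * 6.192)
        # tau starts at the observed time of the second-fastest trial
        assert start.tau == pytest.approx(166.8)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            initial_params(TrialSet("x", [5.0], [100.0]), TWO)


ZERO_NOISE_CASES = [
    (TWO, Params(cs=4.0, d_prime=200.0), [4.5, 5.0, 5.5, 6.0]),
    (THREE, Params(cs=4.1, d_prime=550.0, s_max=7.7), [4.6, 5.2, 5.7, 6.2, 6.8]),
    (EXP, Params(cs=4.4, s_max=7.2, tau=220.0), [4.644, 5.16, 5.676, 6.192]),
]


class TestFit:
    @pytest.mark.parametrize("family,true,speeds", ZERO_NOISE_CASES)
    @pytest.mark.parametrize("formulation", ["ts", "ds"])
    def test_zero_noise_recovery(self, family, true, speeds, formulation):
        """Exact data from any family are recovered by both procedures."""
        trials = exact_trials(family, true, speeds)
        fit = fit_trialset(trials, family, formulation)
        assert fit.converged
        for name in fit.param_names:
            assert getattr(fit.params, name) == pytest.approx(
                getattr(true, name), rel=1e-6
            )

    @pytest.mark.parametrize("formulation", ["ts", "ds"])
    def test_group_mean_cs_bracket(self, group_trials, formulation):
        fit = fit_trialset(group_trials, "2p", formulation)
        assert fit.ok
        assert 4.2 <= fit.params.cs <= 4.7

    @pytest.mark.parametrize("formulation", ["ts", "ds"])
    def test_grid_oracle_agreement(self, group_trials, formulation):
        """Levenberg-Marquardt matches an exhaustive 2-D grid search."""
        fit = fit_trialset(group_trials, "2p", formulation)
        dep = group_trials.times if formulation == "ts" else group_trials.distances
        cs_grid = np.arange(3.5, group_trials.min_speed - 1e-3, 1e-3)
        dp_grid = np.arange(100.0, 500.0, 0.1)
        cs_g, dp_g, sse_g = grid_search_two_param(
            group_trials.speeds, dep, fit.weights, formulation, cs_grid, dp_grid
        )
        # grid minimum within one cs cell; objective gap below one-cell scale
        assert abs(fit.params.cs - cs_g) <= 1e-3
        assert fit.weighted_rss <= sse_g * (1 + 1e-9)
        assert sse_g - fit.weighted_rss <= 1e-3 * fit.weighted_rss

    def test_weighted_rss_and_residual_shapes(self, group_trials):
        fit = fit_trialset(group_trials, "2p", "ts")
        assert fit.weighted_rss >= 0
        assert len(fit.residuals) == fit.n_obs == 4
        assert fit.df == 2
        assert fit.weighted_rss == pytest.approx(
            float(np.sum(fit.weights * fit.residuals**2)), rel=1e-12
        )

    def test_permutation_invariance(self, group_trials):
        fit_a = fit_trialset(group_trials, "3p", "ts")
        order = [2, 0, 3, 1]
        shuffled = TrialSet(
            "perm", group_trials.speeds[order], group_trials.times[order]
        )
        fit_b = fit_trialset(shuffled, "3p", "ts")
        for name in fit_a.param_names:
            assert getattr(fit_a.params, name) == pytest.approx(
                getattr(fit_b.params, name), rel=1e-7
            )

    def test_noise_degrades_cs_monotonically(self):
        """Median |CS error| grows with multiplicative noise CV."""
        medians = []
        for level in (0.03, 0.10, 0.25):
            cfg = SyntheticConfig(
                n_participants=200, noise_model="constant_cv", noise_scale=level, seed=99
            )
            errors = []
            for part in sample_cohort(cfg).participants:
                fit = fit_trialset(part.trials, "2p", "ts")
                if fit.ok:
                    errors.append(abs(fit.params.cs - part.true_params.cs))
            medians.append(np.median(errors))
        assert medians[0] <= medians[1] <= medians[2]


class TestBattery:
    def test_zero_noise_two_param_cells_agree(self, two_param_exact):
        battery = fit_battery(two_param_exact)
        two_cells = [f for f in battery if f.spec.family is TWO]
        assert len(battery) == 6 and len(two_cells) == 2
        assert two_cells[0].params.cs == pytest.approx(two_cells[1].params.cs, abs=1e-9)
        assert two_cells[0].params.d_prime == pytest.approx(
            two_cells[1].params.d_prime, abs=1e-6
        )

    def test_group_mean_cs_ordering(self, group_battery):
        """Family ordering of CS: three-param < two-param < exponential."""
        cs = {
            (f.spec.family, f.spec.formulation): f.params.cs
            for f in group_battery
            if f.ok
        }
        for form in set(k[1] for k in cs):
            assert cs[(THREE, form)] < cs[(TWO, form)] < cs[(EXP, form)]

    def test_three_observations_flag_three_param_cells(self):
        trials = exact_trials(TWO, Params(cs=4.0, d_prime=200.0), [4.5, 5.0, 6.0])
        battery = fit_battery(trials)
        for fit in battery:
            if fit.spec.family is TWO:
                assert fit.converged and fit.standard_errors is not None
            else:
                assert fit.df == 0
                assert "no_dof" in fit.flags
                assert fit.standard_errors is None

    def test_too_few_observations_carried_as_flagged_entry(self):
        trials = exact_trials(TWO, Params(cs=4.0, d_prime=200.0), [4.5, 6.0])
        battery = fit_battery(trials)
        assert len(battery) == 6
        for fit in battery:
            if fit.spec.family is not TWO:
                assert fit.params is None
                assert "insufficient_observations" in fit.flags


class TestSklearnInterface:
    def test_fit_predict_roundtrip(self, two_param_exact):
        reg = CriticalSpeedRegressor(family="2p", formulation="ts")
        X = two_param_exact.speeds[:, None]
        reg.fit(X, two_param_exact.times)
        assert reg.cs_ == pytest.approx(4.0, rel=1e-6)
        assert reg.predict(X) == pytest.approx(two_param_exact.times, rel=1e-6)

    def test_get_set_params_and_clone(self):
        reg = CriticalSpeedRegressor(family="3p", weighting="none", tol=1e-8)
        other = clone(reg)
        assert other.get_params() == reg.get_params()
        other.set_params(family="2p")
        assert other.family == "2p" and reg.family == "3p"

    def test_unknown_weighting_rejected(self, two_param_exact):
        reg = CriticalSpeedRegressor(weighting="bogus")
        with pytest.raises(ValueError, match="weighting"):
            reg.fit(two_param_exact.speeds[:, None], two_param_exact.times)
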