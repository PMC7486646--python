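import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bloodcast import (WeekdayPanel, forecast_ses, init_level, select_alpha,
                       ses_smooth)


def brute_force_alpha(y, grid):
    """Independent exhaustive search: literal recursion per alpha."""
    y = np.asarray(y, float)
    best, best_score = None, np.inf
    for alpha in sorted(grid):
        s = [float(np.mean(y[:3]))]
        for i in range(1, len(y)):
            s.append(alpha * y[i - 1] + (1 - alpha) * s[-1])
        start = 3 if len(y) > 3 else 0
        score = float(np.mean((y[start:] - np.array(s[start:])) ** 2))
        if score < best_score - 1e-15:
            best, best_score = alpha, score
    return best


class TestInitLevel:
    @pytest.mark.parametrize("y, expect", [
        ([100, 110, 120, 500, 600], 110.0),
        ([7, 7, 7, 7], 7.0),
        ([5387, 5155, 5095], pytest.approx(5212.33, abs=0.01)),
    ])
    def test_mean_of_first_three(self, y, expect):
        assert init_level(y) == expect

    def test_needs_three_observations(self):
        with pytest.raises(ValueError, match="3 observations"):
            init_level([1, 2])


class TestSmooth:
    def test_two_step_hand_example(self):
        fit = ses_smooth([10, 12], alpha=0.5, initial_level=10)
        assert np.allclose(fit.smoothed, [10, 10])
        assert fit.forecast_next == pytest.approx(11.0)

    def test_alpha_near_one_tracks_last_observation(self):
        y = np.random.default_rng(0).uniform(50, 150, 30)
        fit = ses_smooth(y, alpha=0.999, initial_level=float(y[:3].mean()))
        assert fit.forecast_next == pytest.approx(y[-1], rel=0.002)

    def test_constant_series_is_fixed_point(self):
        for alpha in (0.01, 0.5, 0.99):
            fit = ses_smooth(np.full(10, 42.0), alpha, 42.0)
            assert np.all(fit.smoothed == 42.0)
            assert fit.forecast_next == 42.0

    def test_alpha_outside_unit_interval_rejected(self):
        for alpha in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError, match="alpha"):
                ses_smooth([1, 2, 3], alpha, 1.0)

    def test_smoothed_values_are_convex_combinations(self):
        """Expanding the recursion 5 steps: weights on {init} + past
        observations are non-negative and sum to 1, so every smoothed value
        lies in the range of what it has seen."""
        y = np.array([3., 9., 1., 7., 5.])
        alpha = 0.3
        init = 4.0
        fit = ses_smooth(y, alpha, init)
        # symbolic expansion: S_k = (1-a)^k init + a sum (1-a)^j y
        for k in range(len(y)):
            weights = [(1 - alpha) ** k] + \
                [alpha * (1 - alpha) ** (k - 1 - j) for j in range(k)]
            assert sum(weights) == pytest.approx(1.0)
            assert fit.smoothed[k] == pytest.approx(
                weights[0] * init + np.dot(weights[1:], y[:k]))
            seen = np.concatenate([[init], y[:k]])
            assert seen.min() - 1e-9 <= fit.smoothed[k] <= seen.max() + 1e-9

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(y=hnp.arrays(float, st.integers(4, 20),
                        elements=st.floats(1, 1e4)),
           alpha=st.floats(0.01, 0.99), c=st.floats(-100, 100))
    def test_shift_equivariance(self, y, alpha, c):
        base = ses_smooth(y, alpha, float(y[:3].mean()))
        shifted = ses_smooth(y + c, alpha, float(y[:3].mean()) + c)
        assert np.allclose(shifted.smoothed, base.smoothed + c, atol=1e-6)
        assert shifted.forecast_next == pytest.approx(base.forecast_next + c,
                                                      abs=1e-6)


class TestSelectAlpha:
    def test_matches_exhaustive_oracle_on_random_series(self):
        rng = np.random.default_rng(1)
        grid = np.round(np.arange(1, 100) / 100.0, 2)
        for _ in range(20):
            level = rng.uniform(100, 1000)
            y = level + rng.normal(0, level * 0.05, size=rng.integers(8, 30)) \
                + np.linspace(0, rng.uniform(-50, 50), 1)[0]
            got = select_alpha(y, grid)
            assert got == brute_force_alpha(y, grid)

    def test_drifting_level_matches_oracle(self):
        rng = np.random.default_rng(2)
        level = 500 + np.cumsum(rng.normal(0, 20, 40))
        y = level + rng.normal(0, 5, 40)
        grid = np.round(np.arange(1, 1000) / 1000.0, 3)
        assert select_alpha(y, grid) == brute_force_alpha(y, grid)

    def test_flat_objective_tie_breaks_to_smallest(self):
        assert select_alpha(np.full(12, 9.0),
                            grid=[0.3, 0.1, 0.7]) == 0.1

    def test_iid_noise_prefers_small_alpha(self):
        hits = 0
        for seed in range(50):
            y = 1000 + np.random.default_rng(seed).normal(0, 50, 60)
            hits += select_alpha(y) < 0.5
        assert hits / 50 >= 0.80

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            select_alpha(np.arange(10.0), grid=[])


class TestForecastPanel:
    def test_constant_columns_forecast_constants(self):
        panel = WeekdayPanel(np.tile(np.arange(1.0, 8.0), (6, 1)))
        fc, fits = forecast_ses(panel, "auto")
        assert np.allclose(fc, np.arange(1.0, 8.0))

    def test_manual_alphas_equal_per_column_smoothing(self):
        rng = np.random.default_rng(3)
        panel = WeekdayPanel(rng.uniform(100, 200, size=(8, 7)))
        alphas = [0.099, 0.200, 0.006, 0.100, 0.003, 0.027, 0.199]
        fc, fits = forecast_ses(panel, alphas)
        for tau in range(1, 8):
            y = panel.column(tau)
            ref = ses_smooth(y, alphas[tau - 1], init_level(y))
            assert fc[tau - 1] == pytest.approx(ref.forecast_next)
            assert fits[tau - 1].alpha == alphas[tau - 1]

    def test_needs_four_weeks(self):
        with pytest.raises(ValueError, match="4 weeks"):
            forecast_ses(WeekdayPanel(np.ones((3, 7))), "auto")
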