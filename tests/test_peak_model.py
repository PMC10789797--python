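"""Peak-model evaluation and the five-parameter least-squares fit."""

import functools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from asgard_ogt import (
    FluorescenceProfile,
    PeakParams,
    SimulationConfig,
    asymmetric_width,
    fit_peak,
    model_fluorescence,
    simulate_binding_profile,
)

GRID = np.arange(0.0, 101.0, 10.0)


class TestAsymmetricWidth:
    def test_midpoint_is_width_average(self, typical_params):
        # logistic is exactly 1/2 at the peak temperature
        assert asymmetric_width(50.0, typical_params) == pytest.approx(15.0)

    def test_limits_are_the_two_widths(self, typical_params):
        assert asymmetric_width(-1e6, typical_params) == pytest.approx(10.0)
        assert asymmetric_width(1e6, typical_params) == pytest.approx(20.0)

    def test_frozen_arithmetic_value(self, typical_params):
        # 10 + 10/(1+e^2), evaluated independently
        assert asymmetric_width(40.0, typical_params) == pytest.approx(11.192029220, abs=1e-6)

    def test_width_bounded_between_s_l_and_s_r(self, typical_params):
        t = np.linspace(-50, 150, 401)
        s = asymmetric_width(t, typical_params)
        assert np.all(s > 10.0) and np.all(s < 20.0)

    def test_equal_widths_give_constant(self):
        p = PeakParams(f0=0.0, f_star=1.0, t_star=30.0, s_l=7.0, s_r=7.0)
        assert np.allclose(asymmetric_width(np.linspace(0, 100, 11), p), 7.0)

    def test_nonfinite_temperature_rejected(self, typical_params):
        with pytest.raises(ValueError):
            asymmetric_width(np.nan, typical_params)


class TestModelFluorescence:
    def test_peak_value_at_t_star(self, typical_params):
        assert model_fluorescence(50.0, typical_params) == pytest.approx(500.0)

    def test_tails_approach_baseline(self, typical_params):
        assert model_fluorescence(-500.0, typical_params) == pytest.approx(100.0, abs=1e-6)
        assert model_fluorescence(700.0, typical_params) == pytest.approx(100.0, abs=1e-6)

    def test_frozen_arithmetic_value(self, typical_params):
        assert model_fluorescence(40.0, typical_params) == pytest.approx(280.032028, abs=1e-4)

    def test_nonfinite_temperature_rejected(self, typical_params):
        with pytest.raises(ValueError):
            model_fluorescence(np.inf, typical_params)

    @settings(max_examples=30, deadline=None)
    @given(
        t_star=st.floats(10, 90),
        s_l=st.floats(3, 25),
        s_r=st.floats(3, 25),
        amp=st.floats(10, 1e4),
    )
    def test_maximum_attained_exactly_at_t_star(self, t_star, s_l, s_r, amp):
        p = PeakParams(f0=50.0, f_star=50.0 + amp, t_star=t_star, s_l=s_l, s_r=s_r)
        t = np.linspace(t_star - 60, t_star + 60, 2001)
        f = model_fluorescence(t, p)
        assert np.all(f <= p.f_star + 1e-9) and np.all(f >= p.f0 - 1e-9)
        assert model_fluorescence(t_star, p) == pytest.approx(p.f_star)
        assert np.max(f) <= model_fluorescence(t_star, p) + 1e-9


class TestPeakParamsInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(f0=0, f_star=1, t_star=50, s_l=-1, s_r=10),
            dict(f0=0, f_star=1, t_star=50, s_l=10, s_r=0),
            dict(f0=0, f_star=1, t_star=50, s_l=10, s_r=10, w=0),
            dict(f0=10, f_star=5, t_star=50, s_l=10, s_r=10),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PeakParams(**kwargs)


def _profile_from(params: PeakParams, noise: float, seed: int, grid=GRID) -> FluorescenceProfile:
    cfg = SimulationConfig(
        temperatures=tuple(grid), noise_sd=noise, noise_relative=True,
        true_params=params, seed=seed,
    )
    return simulate_binding_profile(cfg)[0]


def grid_profile_oracle(profile: FluorescenceProfile, step: float = 0.1, halfwidth: float = 8.0):
    """Brute-force oracle: profile t_star on a fine grid, refitting the other
    four parameters (baseline, amplitude, both widths) at each grid point.

    Independent of fit_peak: its own objective, its own optimizer calls.
    """
    t = np.repeat(profile.temperatures[None, :], profile.n_replicates, axis=0).ravel()
    y = profile.fluorescence.ravel()
    w = 5.0
    s_min = 3.0  # same width floor as the model definition

    def sse_at(t_star, theta4):
        f0, g, ls, lr = theta4
        if np.any(np.abs(theta4[1:]) > 30):
            return np.inf
        s_l, s_r = s_min + np.exp(ls), s_min + np.exp(lr)
        s = s_l + (s_r - s_l) / (1.0 + np.exp(-(t - t_star) / w))
        pred = f0 + np.exp(g) * np.exp(-(((t - t_star) / s) ** 2))
        r = y - pred
        return float(r @ r)

    center = float(profile.temperatures[np.argmax(profile.mean_curve())])
    grid = np.arange(center - halfwidth, center + halfwidth + step / 2, step)
    mean = profile.mean_curve()
    theta0 = np.array(
        [mean.min(), np.log(max(mean.max() - mean.min(), 1e-9)), np.log(7.0), np.log(7.0)]
    )

    def refit(ts, th):
        res = minimize(lambda th_: sse_at(ts, th_), th, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000})
        return res.x, float(res.fun)

    # three candidate chains per grid point (forward / backward warm starts and
    # a cold moment-based start) guard against misconverged 4-parameter refits
    profiled = np.full(grid.size, np.inf)
    th = theta0
    for i, ts in enumerate(grid):
        th, sse = refit(ts, th)
        profiled[i] = min(profiled[i], sse)
    th = theta0
    for i in range(grid.size - 1, -1, -1):
        th, sse = refit(grid[i], th)
        profiled[i] = min(profiled[i], sse)
    for i, ts in enumerate(grid):
        _, sse = refit(ts, theta0)
        profiled[i] = min(profiled[i], sse)
    return float(grid[int(np.argmin(profiled))])


@functools.lru_cache(maxsize=None)
def fit_and_oracle_instance(seed: int):
    """One random 2%-noise assay instance: (fitted t_star, oracle t_star).

    Cached so the module property test and the acceptance suite can assert
    on the same instances without recomputing the brute-force profile.
    """
    rng = np.random.default_rng(1000 + seed)
    params = PeakParams(
        f0=float(rng.uniform(50, 200)),
        f_star=float(rng.uniform(600, 1500)),
        t_star=float(rng.uniform(25, 75)),
        s_l=float(rng.uniform(5, 15)),
        s_r=float(rng.uniform(5, 15)),
        w=5.0,
    )
    profile = _profile_from(params, noise=0.02, seed=seed)
    fit = fit_peak(profile, seed=seed)
    return fit.params.t_star, grid_profile_oracle(profile)


class TestFitPeak:
    def test_noiseless_recovery_is_exact(self, noiseless_profile, typical_params):
        fit = fit_peak(noiseless_profile, seed=0)
        assert fit.converged and fit.identifiable
        assert fit.params.t_star == pytest.approx(typical_params.t_star, abs=1e-3)
        assert fit.sse < 1e-6

    def test_flat_profile_not_identifiable(self, flat_profile):
        fit = fit_peak(flat_profile, seed=0)
        assert not fit.identifiable
        assert fit.t_star is None

    def test_too_few_datapoints_rejected(self):
        prof = FluorescenceProfile("tiny", [0.0, 10.0], [[1.0, 2.0]])
        with pytest.raises(ValueError, match="6 datapoints"):
            fit_peak(prof)

    def test_fit_range_restricts_data(self, noisy_profile):
        fit = fit_peak(noisy_profile, fit_range=(0.0, 60.0), seed=0)
        assert fit.fit_range == (0.0, 60.0)
        assert fit.n_points == 7 * 3

    def test_invalid_fit_range_rejected(self, noisy_profile):
        with pytest.raises(ValueError):
            fit_peak(noisy_profile, fit_range=(60.0, 60.0))

    def test_scale_invariance(self, noisy_profile):
        fit1 = fit_peak(noisy_profile, seed=0)
        scaled = noisy_profile.with_fluorescence(noisy_profile.fluorescence * 3.7)
        fit2 = fit_peak(scaled, seed=0)
        assert fit2.params.t_star == pytest.approx(fit1.params.t_star, abs=0.05)
        assert fit2.params.s_l == pytest.approx(fit1.params.s_l, rel=0.02)
        assert fit2.params.s_r == pytest.approx(fit1.params.s_r, rel=0.02)
        assert fit2.params.f0 == pytest.approx(3.7 * fit1.params.f0, rel=0.02)
        assert fit2.params.f_star == pytest.approx(3.7 * fit1.params.f_star, rel=0.02)

    def test_reflection_swaps_widths(self, noisy_profile):
        fit1 = fit_peak(noisy_profile, seed=0)
        a = 50.0
        reflected = FluorescenceProfile(
            protein_id="reflected",
            temperatures=np.sort(2 * a - noisy_profile.temperatures),
            fluorescence=noisy_profile.fluorescence[:, ::-1],
        )
        fit2 = fit_peak(reflected, seed=0)
        assert fit2.params.t_star == pytest.approx(2 * a - fit1.params.t_star, abs=0.1)
        assert fit2.params.s_l == pytest.approx(fit1.params.s_r, rel=0.05)
        assert fit2.params.s_r == pytest.approx(fit1.params.s_l, rel=0.05)

    def test_sse_never_exceeds_initial_point(self, noisy_profile):
        from asgard_ogt.peak_model import default_init, _residual_sse, _pack
        fit = fit_peak(noisy_profile, seed=0)
        init = default_init(noisy_profile)
        t = np.repeat(noisy_profile.temperatures[None, :], 3, axis=0).ravel()
        y = noisy_profile.fluorescence.ravel()
        assert fit.sse <= _residual_sse(_pack(init), t, y, 5.0) + 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_grid_profiling_oracle(self, seed):
        fit_t, oracle_t = fit_and_oracle_instance(seed)
        assert fit_t == pytest.approx(oracle_t, abs=0.2)
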