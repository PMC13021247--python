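"""Correctness of the Wiener first-passage density, absorption probabilities,
simulator and mixture likelihood, checked against closed forms, independent
series evaluations, and a brute-force Euler oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from _oracles import euler_trials
from ownbias.ddm import (
    DDMParams,
    _decision_time_cdfs,
    _f_standard,
    choice_probability,
    log_likelihood,
    simulate_trials,
    wfpt_density,
)

EULER_SET = dict(v=1.0, a=2.0, z=0.5, t0=0.3)


@pytest.fixture(scope="module")
def euler_sample():
    """One large Euler-simulated sample, shared by the cross-check tests."""
    ch, rt = euler_trials(
        EULER_SET["v"], EULER_SET["a"], EULER_SET["z"], EULER_SET["t0"], 80_000, seed=42
    )
    return ch, rt


class TestDensity:
    def test_zero_before_nondecision_time(self):
        p = DDMParams(v=0.0, a=2.0, z=0.5, t0=0.3)
        for rt in (0.05, 0.2, 0.3):
            assert wfpt_density(rt, "upper", p) == 0.0
            assert wfpt_density(rt, "lower", p) == 0.0

    @pytest.mark.parametrize("a", [0.5, 1.5, 4.0])
    @pytest.mark.parametrize("v", [-4.0, -1.0, 0.0, 2.0, 4.0])
    @pytest.mark.parametrize("z", [0.1, 0.5, 0.9])
    def test_normalization(self, a, v, z):
        """Defective densities over both boundaries integrate to one."""
        p = DDMParams(v=v, a=a, z=z, t0=0.0)
        hi = 40.0 * a  # generous horizon; tail mass beyond is negligible
        total = sum(
            quad(lambda t: wfpt_density(t, b, p), 0, hi, limit=400)[0]
            for b in ("upper", "lower")
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    @settings(max_examples=40, deadline=None)
    @given(
        v=st.floats(-4, 4),
        a=st.floats(0.5, 4),
        z=st.floats(0.1, 0.9),
        t=st.floats(0.01, 5.0),
    )
    def test_reflection_symmetry(self, v, a, z, t):
        """density(t, upper | v, z) == density(t, lower | -v, 1-z) exactly."""
        up = wfpt_density(t, "upper", DDMParams(v=v, a=a, z=z, t0=0.0))
        lo = wfpt_density(t, "lower", DDMParams(v=-v, a=a, z=1 - z, t0=0.0))
        assert up == lo

    def test_series_regimes_agree(self):
        """Small-time and large-time expansions agree in their overlap region.

        Brute-force both sums with many terms (independent of the adaptive
        truncation) and compare against the production evaluation.
        """
        w = 0.37
        for tt in (0.1, 0.25, 0.5, 1.0):
            ks = np.arange(-60, 61)
            small = np.sum((w + 2 * ks) * np.exp(-((w + 2 * ks) ** 2) / (2 * tt)))
            small /= math.sqrt(2 * math.pi * tt**3)
            k = np.arange(1, 200)
            large = math.pi * np.sum(
                k * np.exp(-(k**2) * math.pi**2 * tt / 2) * np.sin(k * math.pi * w)
            )
            assert small == pytest.approx(large, abs=1e-6)
            assert _f_standard(tt, w, 1e-7) == pytest.approx(small, abs=1e-6)

    def test_density_matches_euler_histogram(self, euler_sample):
        """Series density tracks a brute-force simulated RT histogram."""
        ch, rt = euler_sample
        p = DDMParams(**EULER_SET)
        n = len(ch)
        for t_mid in (0.5, 1.0, 2.0):
            width = 0.1
            frac = np.mean((ch == 1) & (np.abs(rt - t_mid) < width / 2))
            dens_est = frac / width
            dens = wfpt_density(t_mid, "upper", p)
            se = math.sqrt(frac * (1 - frac) / n) / width
            assert abs(dens_est - dens) < 4 * se + 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(v=1, a=-1, z=0.5)
        with pytest.raises(ValueError):
            DDMParams(v=1, a=1, z=1.2)
        with pytest.raises(ValueError):
            DDMParams(v=1, a=1, z=0.5, t0=-0.1)
        with pytest.raises(ValueError):
            DDMParams(v=1, a=1, z=0.5, p_out=1.0)


class TestChoiceProbability:
    @pytest.mark.parametrize(
        "params,expected",
        [
            (DDMParams(v=0.0, a=2.0, z=0.5), 0.5),
            (DDMParams(v=0.0, a=1.6, z=0.52), 0.52),
        ],
    )
    def test_zero_drift_equals_relative_start(self, params, expected):
        assert choice_probability(params, "upper") == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(v=st.floats(-4, 4), a=st.floats(0.5, 4), z=st.floats(0.1, 0.9))
    def test_boundary_probabilities_sum_to_one(self, v, a, z):
        p = DDMParams(v=v, a=a, z=z)
        assert choice_probability(p, "upper") + choice_probability(p, "lower") == pytest.approx(1.0)

    def test_matches_euler_simulation(self, euler_sample):
        ch, _ = euler_sample
        p_up = choice_probability(DDMParams(**EULER_SET), "upper")
        se = math.sqrt(p_up * (1 - p_up) / len(ch))
        assert abs(ch.mean() - p_up) < 3 * se + 0.002


class TestSimulator:
    def test_strong_drift_dominates(self):
        ch, _ = simulate_trials(DDMParams(v=5, a=1.5, z=0.5, t0=0.3), 10_000, seed=0)
        assert ch.mean() > 0.95

    def test_nondecision_floor(self):
        _, rt = simulate_trials(DDMParams(v=1, a=2, z=0.5, t0=0.3), 10_000, seed=1)
        assert rt.min() >= 0.3

    def test_choice_fraction_matches_closed_form(self):
        p = DDMParams(v=1, a=2, z=0.5, t0=0.3)
        ch, _ = simulate_trials(p, 100_000, seed=2)
        p_up = choice_probability(p, "upper")
        se = math.sqrt(p_up * (1 - p_up) / 100_000)
        assert abs(ch.mean() - p_up) < 3 * se

    @pytest.mark.parametrize(
        "v,a,z", [(1.0, 2.0, 0.5), (0.0, 1.6, 0.52), (2.5, 1.2, 0.4), (-1.5, 2.5, 0.6), (0.5, 1.0, 0.3)]
    )
    def test_simulator_agrees_with_density_cdf(self, v, a, z):
        """KS distance between simulated RTs and the density-implied CDF."""
        p = DDMParams(v=v, a=a, z=z, t0=0.25)
        ch, rt = simulate_trials(p, 100_000, seed=7)
        ts, c_up, c_lo = _decision_time_cdfs(v, a, z)
        for b, cdf in ((1, c_up), (0, c_lo)):
            x = np.sort(rt[ch == b]) - 0.25
            if len(x) < 2000:
                continue
            theo = np.interp(x, ts, cdf) / cdf[-1]
            emp = np.arange(1, len(x) + 1) / len(x)
            # 0.01 systematic bound plus the per-boundary sampling component
            assert np.max(np.abs(theo - emp)) < 0.01 + 1.36 / math.sqrt(len(x))

    def test_euler_oracle_agrees_with_density_cdf(self, euler_sample):
        """Independent Euler simulation matches the series-implied CDF."""
        ch, rt = euler_sample
        ts, c_up, _ = _decision_time_cdfs(EULER_SET["v"], EULER_SET["a"], EULER_SET["z"])
        x = np.sort(rt[ch == 1]) - EULER_SET["t0"]
        theo = np.interp(x, ts, c_up) / c_up[-1]
        emp = np.arange(1, len(x) + 1) / len(x)
        assert np.max(np.abs(theo - emp)) < 0.01

    def test_contaminants_inserted(self):
        p = DDMParams(v=1, a=2, z=0.5, t0=0.4, p_out=0.1)
        ch, rt = simulate_trials(p, 20_000, seed=3)
        frac_early = np.mean(rt < 0.4)  # only contaminants can beat t0
        # expected ~ p_out * t0 / horizon ~ 0.1 * 0.4 / 3.7
        assert 0.004 < frac_early < 0.025

    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_trials(DDMParams(v=0, a=1, z=0.5), 0)


class TestLogLikelihood:
    def test_single_trial_equals_log_density(self):
        p = DDMParams(v=1, a=2, z=0.5, t0=0.3)
        ll = log_likelihood((np.array([1]), np.array([0.8])), p, t_max=5.0)
        assert ll == pytest.approx(math.log(wfpt_density(0.8, "upper", p)))

    def test_contaminant_floor_for_fast_rt(self):
        p = DDMParams(v=1, a=2, z=0.5, t0=0.3, p_out=0.05)
        t_max = 4.0
        ll = log_likelihood((np.array([0]), np.array([0.1])), p, t_max=t_max)
        assert ll == pytest.approx(math.log(0.05 / t_max / 2))

    def test_rt_before_t0_without_mixture_is_neg_inf(self):
        p = DDMParams(v=1, a=2, z=0.5, t0=0.3, p_out=0.0)
        ll = log_likelihood((np.array([1]), np.array([0.1])), p)
        assert ll == -math.inf

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood((np.array([]), np.array([])), DDMParams(v=0, a=1, z=0.5))

    def test_likelihood_concentrates_at_generating_params(self):
        """Generating parameters beat drift-perturbed ones on almost every
        replicate dataset (likelihood concentration)."""
        p = DDMParams(v=1.0, a=2.0, z=0.5, t0=0.3)
        wins = 0
        n_rep = 100
        rng = np.random.default_rng(12)
        for _ in range(n_rep):
            trials = simulate_trials(p, 100, rng=rng)
            ll0 = log_likelihood(trials, p, t_max=5.0)
            ll_hi = log_likelihood(trials, DDMParams(v=2.0, a=2.0, z=0.5, t0=0.3), t_max=5.0)
            ll_lo = log_likelihood(trials, DDMParams(v=0.0, a=2.0, z=0.5, t0=0.3), t_max=5.0)
            wins += ll0 > ll_hi and ll0 > ll_lo
        assert wins >= 95

    def test_response_recoding_maps_to_reflected_params(self):
        """Relabeling the boundaries is equivalent to (v, z) -> (-v, 1-z)."""
        p = DDMParams(v=0.8, a=1.8, z=0.6, t0=0.3)
        ch, rt = simulate_trials(p, 500, seed=5)
        p_ref = DDMParams(v=-0.8, a=1.8, z=0.4, t0=0.3)
        ll = log_likelihood((ch, rt), p, t_max=5.0)
        ll_ref = log_likelihood((1 - ch, rt), p_ref, t_max=5.0)
        assert ll == pytest.approx(ll_ref, rel=1e-12)
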