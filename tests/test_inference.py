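"""Hierarchical sampler: reproducibility, deviance cross-checks against the
reference likelihood, recovery on a small cohort, DIC, directional posterior
probabilities and Bayes factors, and the z ~ covariate regression."""

import math

import numpy as np
import pytest

from ownbias.ddm import DDMParams, log_likelihood
from ownbias.inference import (
    PosteriorSamples,
    _deviance_at,
    _ilogit,
    bayes_factor,
    compute_dic,
    condition_mean_drift,
    directional_prob,
    format_bf,
    regress_z_on_pse,
    sample_posterior,
)
from ownbias.models import ModelSpec, build_design
from ownbias.synth import generate_experiment, recovery_config


def _tiny_design(variant="M2", seed=8, n_subjects=2):
    trials, truth = generate_experiment(
        recovery_config(n_subjects=n_subjects, blocks=1, seed=seed)
    )
    return build_design(trials, ModelSpec.from_variant(variant)), truth


def _fake_posterior(draws_by_name):
    group = {k: np.asarray(v, float)[None, :] for k, v in draws_by_name.items()}
    n = next(iter(group.values())).shape[1]
    return PosteriorSamples(
        group=group, subject={}, deviance=np.zeros((1, n)),
        n_samples=n, n_burn=0, seed=0, design=None,
    )


class TestSampler:
    def test_same_seed_reproduces_different_seed_differs(self):
        design, _ = _tiny_design()
        a = sample_posterior(design, n_samples=300, n_burn=100, seed=42)
        b = sample_posterior(design, n_samples=300, n_burn=100, seed=42)
        c = sample_posterior(design, n_samples=300, n_burn=100, seed=43)
        np.testing.assert_array_equal(a.get("z"), b.get("z"))
        assert not np.array_equal(a.get("z"), c.get("z"))

    def test_burn_must_precede_samples(self):
        design, _ = _tiny_design()
        with pytest.raises(ValueError):
            sample_posterior(design, n_samples=100, n_burn=100)

    def test_regression_requires_free_z(self):
        design, _ = _tiny_design("M1")
        with pytest.raises(ValueError):
            sample_posterior(design, n_samples=100, n_burn=10,
                             x_reg=np.zeros(design.n_subjects))

    def test_multichain_shapes_and_rhat(self):
        design, _ = _tiny_design()
        post = sample_posterior(design, n_samples=300, n_burn=100,
                                seed=2, n_chains=2)
        assert post.n_chains == 2
        assert post.get("z").size == 2 * 200
        assert np.isfinite(post.rhat("z"))

    def test_summary_lists_expected_parameters(self, m2_posterior):
        s = m2_posterior.summary()
        names = set(s["parameter"])
        assert {"z", "a", "t0", "sigma_v", "v[ownership,45]"} <= names
        assert (s["q2_5"] <= s["mean"]).all() and (s["mean"] <= s["q97_5"]).all()


class TestDevianceIdentity:
    def test_deviance_matches_reference_likelihood(self, small_cohort):
        """The numba deviance equals -2x the pure-Python mixture likelihood
        summed over every subject x morph cell."""
        trials, _ = small_cohort
        design = build_design(trials, ModelSpec.from_variant("M2"))
        rng = np.random.default_rng(0)
        n_s, n_m = design.n_subjects, design.n_morph
        v_s = rng.normal(0, 1, (n_s, n_m))
        a_s = rng.uniform(1.2, 2.0, n_s)
        z_s = rng.uniform(0.4, 0.6, n_s)
        t0_s = rng.uniform(0.2, 0.3, n_s)
        dev = _deviance_at(design.rt, design.upper, design.cell_start,
                           design.cell_count, v_s, a_s, z_s, t0_s,
                           design.p_out, design.t_max)
        ll = 0.0
        for s in range(n_s):
            for m in range(n_m):
                st, ct = design.cell_start[s, m], design.cell_count[s, m]
                p = DDMParams(v=v_s[s, m], a=a_s[s], z=z_s[s], t0=t0_s[s],
                              p_out=design.p_out)
                ll += log_likelihood(
                    (design.upper[st:st + ct], design.rt[st:st + ct]),
                    p, t_max=design.t_max,
                )
        assert dev == pytest.approx(-2.0 * ll, rel=1e-9)


class TestRecovery:
    def test_group_z_recovered(self, m2_posterior, small_cohort):
        """Cohort generated at group z = 0.55; posterior mean lands near it
        and clearly above the unbiased 0.5."""
        _, truth = small_cohort
        z_draws = m2_posterior.get("z")
        assert z_draws.mean() == pytest.approx(truth["z"].mean(), abs=0.04)
        assert directional_prob(m2_posterior, "z", 0.5) < 0.05

    def test_subject_z_tracks_truth(self, m2_posterior, small_cohort):
        _, truth = small_cohort
        z_hat = _ilogit(m2_posterior.subject_post("logit_z").mean(axis=0))
        assert np.abs(z_hat - truth["z"].to_numpy()).max() < 0.08

    def test_folded_drift_recovers_generative_scale(self, m2_posterior, small_cohort):
        # folded mean of the linear map = half the generative v_max
        _, truth = small_cohort
        target = 0.5 * truth["v_max"].mean()
        got = condition_mean_drift(m2_posterior, "ownership")
        assert got == pytest.approx(target, abs=0.15)


class TestDic:
    def test_components_consistent(self, m2_posterior):
        r = compute_dic(m2_posterior)
        assert math.isfinite(r.dic)
        assert r.p_d > 0  # posterior-mean fit beats the average draw
        assert r.dic == pytest.approx(r.d_hat + 2 * r.p_d)
        assert r.dic == pytest.approx(r.d_bar + r.p_d)

    def test_biased_cohort_prefers_free_z(self, m2_posterior, small_cohort):
        """On z = 0.55 data the free-z model beats the z = 0.5 model."""
        trials, _ = small_cohort
        d1 = build_design(trials, ModelSpec.from_variant("M1"))
        post1 = sample_posterior(d1, n_samples=800, n_burn=300, seed=1)
        assert compute_dic(m2_posterior).dic < compute_dic(post1).dic


class TestEvidenceSummaries:
    def test_directional_prob_on_known_draws(self):
        post = _fake_posterior({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.5] * 4})
        assert directional_prob(post, "x", "y") == 0.5
        assert directional_prob(post, "x", 0.0) == 0.0
        assert directional_prob(post, "x", 10.0) == 1.0
        with pytest.raises(KeyError):
            post.get("missing")

    @pytest.mark.parametrize(
        "p,bf_rounded",
        [(0.045, 21), (0.002, 499), (0.019, 52), (0.081, 11), (0.11, 8)],
    )
    def test_bayes_factor_rounding(self, p, bf_rounded):
        assert round(bayes_factor(p)) == bf_rounded
        assert format_bf(bayes_factor(p)) == str(bf_rounded)

    def test_bayes_factor_bounds(self):
        assert bayes_factor(0.0) == math.inf
        assert bayes_factor(1.0) == 0.0
        assert format_bf(math.inf) == ">999"
        assert format_bf(1500.0) == ">999"
        with pytest.raises(ValueError):
            bayes_factor(-0.1)


class TestRegression:
    def test_slope_sign_tracks_constructed_covariate(self, small_cohort):
        """A covariate built to decrease in the true z yields a negative
        slope posterior; its mirror image flips the sign."""
        trials, truth = small_cohort
        z_true = truth.set_index("participant")["z"]
        pse_down = {p: 100.0 * (1.0 - z) for p, z in z_true.items()}
        post = regress_z_on_pse(trials, pse_down, n_samples=600, n_burn=200, seed=3)
        assert {"z_intercept", "z_slope"} <= set(post.names)
        p_neg = np.mean(post.get("z_slope") < 0)
        pse_up = {p: 100.0 * z for p, z in z_true.items()}
        post_up = regress_z_on_pse(trials, pse_up, n_samples=600, n_burn=200, seed=3)
        p_neg_up = np.mean(post_up.get("z_slope") < 0)
        assert p_neg > 0.8 and p_neg_up < 0.2

    def test_constant_predictor_rejected(self, small_cohort):
        trials, truth = small_cohort
        flat = {p: 50.0 for p in truth["participant"]}
        with pytest.raises(ValueError):
            regress_z_on_pse(trials, flat)
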