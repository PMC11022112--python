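"""The 5-PL curve, model builders, priors, and log-density machinery."""

import numpy as np
import pytest

import mpmath

from valtrans.model import (
    FivePLParams,
    ModelSpec,
    PRIOR_CONSTANTS,
    build_5pl_model,
    build_en_model,
    build_linear_model,
    five_pl,
    log_density_constrained,
    sample_prior,
)
from valtrans.screening import numbing_z_scores


class TestFivePL:
    def test_symmetric_midpoint(self):
        # with g=1 the curve crosses (a+d)/2 exactly at x=c
        assert five_pl(2.5, 0.0, 2.0, 2.5, 0.5, 1.0) == pytest.approx(0.25)

    def test_asymptotes(self):
        p = FivePLParams(a=0.05, b=1.8, c=2.2, d=0.48, g=2.5)
        assert five_pl(1e-9, *p.as_tuple()) == pytest.approx(p.a, abs=1e-6)
        assert five_pl(1e9, *p.as_tuple()) == pytest.approx(p.d, abs=1e-6)

    def test_against_high_precision_evaluation(self, rng):
        """Direct mpmath evaluation of the formula, 1000 random valid points."""
        mpmath.mp.dps = 50
        for _ in range(1000):
            a = rng.uniform(0.01, 0.5)
            b = rng.uniform(0.5, 5.0)
            c = rng.uniform(0.6, 4.9)
            d = rng.uniform(0.3, 1.0)
            g = rng.uniform(0.2, 5.0)
            x = rng.uniform(0.05, 8.0)
            expected = mpmath.mpf(d) + (mpmath.mpf(a) - mpmath.mpf(d)) / (
                1 + (mpmath.mpf(x) / mpmath.mpf(c)) ** mpmath.mpf(b)
            ) ** mpmath.mpf(g)
            got = five_pl(x, a, b, c, d, g)
            assert abs(got - float(expected)) <= 1e-12 * max(1.0, abs(float(expected)))

    def test_monotone_when_a_below_d(self, rng):
        xs = np.linspace(0.05, 8.0, 400)
        for _ in range(50):
            a = rng.uniform(0.0, 0.3)
            d = rng.uniform(a + 0.05, 1.0)
            vals = five_pl(xs, a, rng.uniform(0.5, 4), rng.uniform(0.6, 4.9), d,
                           rng.uniform(0.2, 4))
            assert np.all(np.diff(vals) >= -1e-12)
            assert np.all((vals > a - 1e-12) & (vals < d + 1e-12))

    def test_g_one_equals_four_pl(self, rng):
        xs = np.linspace(0.1, 6.0, 100)
        a, b, c, d = 0.1, 2.0, 2.5, 0.6
        fourpl = d + (a - d) / (1.0 + (xs / c) ** b)
        np.testing.assert_allclose(five_pl(xs, a, b, c, d, 1.0), fourpl, rtol=1e-14)

    def test_domain_error(self):
        with pytest.raises(ValueError, match="x > 0"):
            five_pl(-1.0, 0.1, 2.0, 2.5, 0.6, 1.0)

    def test_param_bounds_enforced(self):
        with pytest.raises(ValueError):
            FivePLParams(a=0.1, b=0.3, c=2.0, d=0.6, g=1.0)


class TestModelStructure:
    def test_5pl_parameter_count(self, small_negative):
        spec = build_5pl_model(small_negative["ratings"], small_negative["norms"])
        dens = spec.log_density()
        P = spec.n_participants
        # 6 group-level + 5 participant vectors + noise scale
        assert dens.n_dim == 6 + 5 * P + 1
        dims = dens.param_dims()
        assert sum(1 for d in dims.values() if d == ()) == 7
        assert sum(1 for d in dims.values() if d == ("participant",)) == 5

    def test_linear_parameter_count(self, small_negative):
        spec = build_linear_model(small_negative["ratings"], small_negative["norms"])
        assert spec.log_density().n_dim == 2 + 2 * spec.n_participants + 1

    def test_en_model_reduces_to_base_when_coefficient_zero(self, small_negative):
        ratings, norms = small_negative["ratings"], small_negative["norms"]
        pidx = sorted(ratings["participant_id"].unique())
        nz = numbing_z_scores(np.arange(len(pidx)))
        base = build_5pl_model(ratings, norms, pidx).log_density()
        en = build_en_model(
            ratings, norms, pidx, nz, estimate_slope_sd=False
        ).log_density()
        rng = np.random.default_rng(0)
        z = base.initial_point(rng, 0.2)
        z_en = np.concatenate([z, [0.0]])  # EN coefficient pinned at 0
        lp_base, g_base = base.logp_grad(z)
        lp_en, g_en = en.logp_grad(z_en)
        # likelihood identical; EN adds only its own Normal(0,1) prior term
        assert lp_en == pytest.approx(lp_base, abs=1e-9)
        np.testing.assert_allclose(g_en[: len(z)], g_base, atol=1e-9)

    def test_en_covariate_length_mismatch(self, small_negative):
        ratings, norms = small_negative["ratings"], small_negative["norms"]
        pidx = sorted(ratings["participant_id"].unique())
        with pytest.raises(ValueError, match="numbing_z"):
            build_en_model(ratings, norms, pidx, np.zeros(3) + [0.5, -0.5, 0.0])

    def test_uncentred_numbing_rejected(self, small_negative):
        ratings, norms = small_negative["ratings"], small_negative["norms"]
        pidx = sorted(ratings["participant_id"].unique())
        with pytest.raises(ValueError, match="centred"):
            build_en_model(ratings, norms, pidx, np.ones(len(pidx)))

    def test_data_validation(self, small_negative):
        ratings = small_negative["ratings"].copy()
        ratings.loc[0, "rating"] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_5pl_model(ratings, small_negative["norms"])

    def test_serialization_roundtrip_lossless(self, small_negative):
        spec = build_5pl_model(
            small_negative["ratings"],
            small_negative["norms"],
            priors={"mu_b": {"mu": 2.5}},
        )
        back = ModelSpec.from_json(spec.to_json())
        assert back.model_kind == spec.model_kind
        assert back.priors == spec.priors
        np.testing.assert_array_equal(back.x, spec.x)
        np.testing.assert_array_equal(back.y, spec.y)
        np.testing.assert_array_equal(back.participant_idx, spec.participant_idx)

    def test_printed_prior_constants_present(self):
        # group-level hyperprior block
        assert PRIOR_CONSTANTS["alpha1"] == {"mu": 2.0, "sd": 1.0, "lower": 1.0}
        assert PRIOR_CONSTANTS["alpha2"] == {"mu": 10.0, "sd": 1.0}
        assert PRIOR_CONSTANTS["mu_g"] == {"mu": 4.0, "sd": 1.0, "lower": 1.0}
        assert PRIOR_CONSTANTS["mu_d"]["lower"] == 0.0
        # participant-level truncations differ from the group-level ones
        assert PRIOR_CONSTANTS["d"]["lower"] == 0.5
        assert PRIOR_CONSTANTS["g"]["lower"] == 0.8
        assert PRIOR_CONSTANTS["c"] == {"sd": 1.0, "lower": 0.5, "upper": 5.0}
        assert PRIOR_CONSTANTS["linear_mu_a"] == {"mu": 0.0, "sd": 0.2, "lower": 0.0}
        assert PRIOR_CONSTANTS["linear_mu_b"] == {"mu": 0.0, "sd": 0.5, "lower": 0.0}


class TestLogDensity:
    def _valid_point(self, P):
        return {
            "alpha1": 2.0,
            "alpha2": 10.0,
            "mu_b": 2.0,
            "mu_c": 2.0,
            "mu_d": 1.0,
            "mu_g": 4.0,
            "a": np.full(P, 0.1),
            "b": np.full(P, 1.5),
            "c": np.full(P, 2.5),
            "d": np.full(P, 0.7),
            "g": np.full(P, 2.0),
            "sigma": 0.1,
        }

    def test_finite_inside_bounds_neg_inf_outside(self, small_negative):
        spec = build_5pl_model(small_negative["ratings"], small_negative["norms"])
        P = spec.n_participants
        point = self._valid_point(P)
        assert np.isfinite(log_density_constrained(spec, point))
        for bad_key, bad_val in [
            ("mu_b", 0.9),  # below hyperprior bound 1
            ("alpha2", -1.0),  # positivity guard
            ("sigma", -0.1),
        ]:
            bad = dict(point, **{bad_key: bad_val})
            assert log_density_constrained(spec, bad) == -np.inf
        bad = dict(point, b=np.full(P, 0.4))  # below participant bound 0.5
        assert log_density_constrained(spec, bad) == -np.inf

    @pytest.mark.parametrize("kind", ["fivepl", "linear", "en", "en_age_interaction"])
    def test_gradient_matches_finite_differences(self, small_negative, kind, rng):
        ratings, norms = small_negative["ratings"], small_negative["norms"]
        pidx = sorted(ratings["participant_id"].unique())
        nz = numbing_z_scores(np.arange(len(pidx)))
        az = numbing_z_scores(rng.normal(size=len(pidx)))
        if kind == "fivepl":
            spec = build_5pl_model(ratings, norms)
        elif kind == "linear":
            spec = build_linear_model(ratings, norms)
        elif kind == "en":
            spec = build_en_model(ratings, norms, pidx, nz)
        else:
            spec = build_en_model(ratings, norms, pidx, nz, "age_interaction", az)
        dens = spec.log_density()
        for trial in range(3):
            z = dens.initial_point(rng, 0.5)
            lp, grad = dens.logp_grad(z)
            assert np.isfinite(lp)
            eps = 1e-6
            fd = np.empty_like(z)
            for i in range(z.size):
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                fd[i] = (dens.logp_grad(zp)[0] - dens.logp_grad(zm)[0]) / (2 * eps)
            np.testing.assert_allclose(grad, fd, rtol=5e-5, atol=5e-5)

    @pytest.mark.parametrize("kind", ["fivepl", "linear", "en_est_sd"])
    def test_compiled_kernel_matches_reference(self, small_negative, kind, rng):
        """The numba fast path and the numpy/scipy reference are one density."""
        ratings, norms = small_negative["ratings"], small_negative["norms"]
        pidx = sorted(ratings["participant_id"].unique())
        nz = numbing_z_scores(np.arange(len(pidx)))
        spec = {
            "fivepl": lambda: build_5pl_model(ratings, norms),
            "linear": lambda: build_linear_model(ratings, norms),
            "en_est_sd": lambda: build_en_model(ratings, norms, pidx, nz),
        }[kind]()
        dens = spec.log_density()
        for _ in range(5):
            z = dens.initial_point(rng, 0.6)
            lp_f, g_f = dens.logp_grad(z)
            lp_r, g_r = dens.logp_grad_reference(z)
            assert lp_f == pytest.approx(lp_r, rel=1e-9, abs=1e-7)
            np.testing.assert_allclose(g_f, g_r, rtol=5e-7, atol=5e-7)

    def test_linear_with_zero_slope_is_constant(self):
        # mean function reduces to the intercept everywhere
        xs = np.array([0.5, 2.0, 5.0])
        assert np.ptp(0.3 + 0.0 * xs) == 0.0


class TestPriorPredictive:
    def test_5pl_prior_draws_respect_truncations(self, small_negative):
        spec = build_5pl_model(small_negative["ratings"], small_negative["norms"])
        draws = sample_prior(spec, n_draws=300, seed=1)
        assert np.all((draws["a"] > 0) & (draws["a"] < 1))
        assert np.all(draws["b"] >= 0.5)
        assert np.all((draws["c"] >= 0.5) & (draws["c"] <= 5.0))
        assert np.all(draws["d"] >= 0.5)
        assert np.all(draws["g"] >= 0.8)
        assert np.all(draws["alpha1"] >= 1.0)
        assert np.all(draws["mu_g"] >= 1.0)

    def test_linear_prior_draws_nonnegative(self, small_negative):
        spec = build_linear_model(small_negative["ratings"], small_negative["norms"])
        draws = sample_prior(spec, n_draws=300, seed=2)
        assert np.all(draws["a"] >= 0) and np.all(draws["b"] >= 0)
        assert np.all(draws["mu_a"] >= 0) and np.all(draws["mu_b"] >= 0)
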