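"""The sampler, HPD intervals, group contrasts, and convergence diagnostics."""

import arviz as az
import numpy as np
import pytest

from valtrans.inference import (
    ConvergenceWarning,
    PosteriorDraws,
    SamplerConfig,
    compare_groups,
    diagnostics_report,
    fit,
    hpd,
)
from valtrans.model import build_5pl_model
from valtrans.nuts import sample_nuts


class _ConjugateNormal:
    """y_i ~ N(mu, sigma known), mu ~ N(m0, t0): posterior is analytic."""

    n_dim = 1

    def __init__(self, y, sigma=0.5, m0=0.0, t0=2.0):
        self.y = np.asarray(y)
        self.sigma, self.m0, self.t0 = sigma, m0, t0
        prec = 1.0 / t0**2 + len(y) / sigma**2
        self.post_var = 1.0 / prec
        self.post_mean = self.post_var * (m0 / t0**2 + self.y.sum() / sigma**2)

    def logp_grad(self, z):
        mu = z[0]
        g = -(mu - self.m0) / self.t0**2 - (mu - self.y).sum() / self.sigma**2
        lp = -0.5 * ((mu - self.m0) / self.t0) ** 2 - 0.5 * (
            ((self.y - mu) / self.sigma) ** 2
        ).sum()
        return float(lp), np.array([g])

    def initial_point(self, rng, jitter=0.3):
        return rng.normal(size=1)


class TestSampler:
    def test_conjugate_posterior_recovered(self, rng):
        y = rng.normal(1.3, 0.5, size=40)
        m = _ConjugateNormal(y)
        Z, _ = sample_nuts(m, draws=1500, tune=500, chains=2, seed=3)
        draws = Z.ravel()
        se = np.sqrt(m.post_var / len(draws)) * 5  # generous Monte-Carlo slack
        assert draws.mean() == pytest.approx(m.post_mean, abs=max(se, 0.01))
        assert draws.std() == pytest.approx(np.sqrt(m.post_var), rel=0.1)

    def test_deterministic_under_fixed_seed(self, small_negative):
        spec = build_5pl_model(small_negative["ratings"], small_negative["norms"])
        cfg = SamplerConfig(draws=40, tune=60, chains=2, seed=5)
        d1 = fit(spec, cfg)
        d2 = fit(spec, cfg)
        np.testing.assert_array_equal(
            d1.idata.posterior["mu_b"].values, d2.idata.posterior["mu_b"].values
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(draws=0)
        with pytest.raises(ValueError):
            SamplerConfig(target_accept=1.5)

    def test_zarr_roundtrip_preserves_fit(self, small_negative, tmp_path):
        """Posterior, sample stats and pointwise log-lik survive persistence."""
        spec = build_5pl_model(small_negative["ratings"], small_negative["norms"])
        with pytest.warns(ConvergenceWarning):
            d = fit(spec, SamplerConfig(draws=30, tune=50, chains=2, seed=9))
        store = tmp_path / "fit.zarr"
        d.to_zarr(store)
        back = PosteriorDraws.from_zarr(store)
        assert back.model_kind == "fivepl"
        np.testing.assert_allclose(
            back.idata.posterior["mu_b"].values, d.idata.posterior["mu_b"].values
        )
        assert "log_likelihood" in back.idata.groups()
        assert "sample_stats" in back.idata.groups()

    def test_curve_overlay_and_density_plots(self, small_negative, tmp_path):
        """Plot helpers render a figure from a fitted posterior."""
        import matplotlib

        matplotlib.use("Agg")
        from valtrans.plots import plot_curve_overlay, plot_posterior_density

        spec = build_5pl_model(small_negative["ratings"], small_negative["norms"])
        with pytest.warns(ConvergenceWarning):
            d = fit(spec, SamplerConfig(draws=30, tune=50, chains=2, seed=9))
        ax = plot_curve_overlay(d, small_negative["ratings"], small_negative["norms"])
        ax.figure.savefig(tmp_path / "overlay.png")
        ax2 = plot_posterior_density(d, "mu_b")
        ax2.figure.savefig(tmp_path / "density.png")
        assert (tmp_path / "overlay.png").stat().st_size > 0

    def test_short_fit_warns_about_convergence_bar(self, small_negative):
        """A deliberately tiny run cannot reach ESS > 1000 and must say so."""
        spec = build_5pl_model(small_negative["ratings"], small_negative["norms"])
        with pytest.warns(ConvergenceWarning):
            fit(spec, SamplerConfig(draws=30, tune=50, chains=2, seed=2))


class TestHpd:
    def test_standard_normal_89(self, rng):
        draws = rng.standard_normal(1_000_000)
        lo, hi = hpd(draws, 0.89)
        # symmetric unimodal: HPD equals the central interval +-1.598; the
        # half-width estimate is sharp, the position jitters O(n^-1/3)
        assert (hi - lo) / 2 == pytest.approx(1.598, abs=0.01)
        assert lo == pytest.approx(-1.598, abs=0.04)
        assert hi == pytest.approx(1.598, abs=0.04)

    def test_agrees_with_arviz_hdi(self, rng):
        # same estimator up to a one-sample difference in the window size
        draws = rng.gamma(2.0, 1.0, size=20_000)
        lo, hi = hpd(draws, 0.89)
        ref = az.hdi(draws, hdi_prob=0.89)
        assert lo == pytest.approx(ref[0], abs=5e-3)
        assert hi == pytest.approx(ref[1], abs=5e-3)

    def test_constant_samples_zero_width(self):
        lo, hi = hpd(np.full(500, 3.2), 0.89)
        assert lo == hi == 3.2

    def test_mass_near_one_spans_range(self, rng):
        draws = rng.standard_normal(1000)
        lo, hi = hpd(draws, 0.999999)
        assert lo == draws.min() and hi == draws.max()

    def test_monotone_in_mass(self, rng):
        draws = rng.standard_normal(50_000)
        widths = [np.diff(hpd(draws, m))[0] for m in (0.5, 0.7, 0.89, 0.95)]
        assert np.all(np.diff(widths) > 0)

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            hpd(np.arange(200.0), 1.2)


def _fake_draws(rng, loc, name="mu_b", n=4000):
    arr = rng.normal(loc, 0.1, size=(2, n // 2))
    idata = az.from_dict(posterior={name: arr})
    return PosteriorDraws(idata=idata, model_kind="fivepl")


class TestCompareGroups:
    def test_self_comparison_not_robust(self, rng):
        d = _fake_draws(rng, 1.5)
        comps = compare_groups(d, d, ["mu_b"])
        assert comps[0].mean == pytest.approx(0.0)
        assert not comps[0].robust

    def test_antisymmetric(self, rng):
        d1 = _fake_draws(rng, 1.2)
        d2 = _fake_draws(rng, 1.5)
        ab = compare_groups(d1, d2, ["mu_b"])[0]
        ba = compare_groups(d2, d1, ["mu_b"])[0]
        assert ab.hpd_low == pytest.approx(-ba.hpd_high)
        assert ab.hpd_high == pytest.approx(-ba.hpd_low)
        assert ab.robust and ba.robust
        assert ab.hpd_high < 0 < ba.hpd_low  # TEC - pPTSD negative direction

    def test_pairing_invariance(self, rng):
        """Pairwise vs re-randomized pairing: same interval within MC error."""
        d1 = _fake_draws(rng, 1.2, n=40_000)
        d2 = _fake_draws(rng, 1.5, n=40_000)
        c = compare_groups(d1, d2, ["mu_b"])[0]
        s1, s2 = d1.stacked("mu_b"), d2.stacked("mu_b")
        perm = np.random.default_rng(0).permutation(len(s2))
        lo, hi = hpd(s1 - s2[perm], 0.89)
        assert c.hpd_low == pytest.approx(lo, abs=0.02)
        assert c.hpd_high == pytest.approx(hi, abs=0.02)

    def test_unequal_draw_counts_subsampled(self, rng):
        d1 = _fake_draws(rng, 1.2, n=4000)
        d2 = _fake_draws(rng, 1.5, n=2000)
        c = compare_groups(d1, d2, ["mu_b"])[0]
        assert len(c.difference) == 2000

    def test_missing_parameter_named(self, rng):
        d1 = _fake_draws(rng, 1.2)
        d2 = _fake_draws(rng, 1.5, name="other")
        with pytest.raises(KeyError, match="mu_b"):
            compare_groups(d1, d2, ["mu_b"])


class TestParameterRecovery:
    def test_hypermeans_recovered_across_seeds(self):
        """Group-level slope and inflection means land within 3 posterior SDs
        of the generating values in most seeds.

        The generator draws participants from the model's own truncated
        populations (unit SDs) so the hypermean estimands equal the
        generating values; 60 participants, 12 images.
        """
        import warnings

        from valtrans.inference import ConvergenceWarning
        from valtrans.synthetic_data import (
            GeneratorConfig,
            GroupParams,
            generate_norms,
            generate_participants,
        )

        true_mu_b, true_mu_c = 1.6, 2.5
        hits_b = hits_c = 0
        for seed in range(1, 6):
            norms = generate_norms(n_images=12, n_positive=0, seed=seed)
            cfg = GeneratorConfig(
                n_per_group=60,
                seed=seed,
                n_images=12,
                n_positive=0,
                en_slope_coeff=0.0,
                groups={
                    "TEC": GroupParams(
                        mu_b=true_mu_b, sd_b=1.0, mu_c=true_mu_c, sd_c=1.0
                    )
                },
            )
            ratings, _, _ = generate_participants(cfg, norms)
            spec = build_5pl_model(ratings, norms)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                d = fit(spec, SamplerConfig(draws=250, tune=250, chains=2, seed=seed))
            mu_b = d.stacked("mu_b")
            mu_c = d.stacked("mu_c")
            hits_b += abs(mu_b.mean() - true_mu_b) <= 3 * mu_b.std()
            hits_c += abs(mu_c.mean() - true_mu_c) <= 3 * mu_c.std()
        assert hits_b >= 4
        assert hits_c >= 4


class TestDiagnostics:
    def _draws_from(self, arr, name="theta"):
        return PosteriorDraws(idata=az.from_dict(posterior={name: arr}))

    def test_iid_chains_pass_the_bar(self, rng):
        d = self._draws_from(rng.standard_normal((4, 1000)))
        rep = diagnostics_report(d)
        row = rep.iloc[0]
        assert 1.0 <= row["rhat"] < 1.01
        assert not row["flagged"]
        # ESS of i.i.d. draws is close to the nominal draw count
        assert row["ess_bulk"] == pytest.approx(4000, rel=0.2)

    def test_offset_chain_flagged(self, rng):
        arr = rng.standard_normal((4, 1000))
        arr[0] += 10.0
        rep = diagnostics_report(self._draws_from(arr))
        assert rep.iloc[0]["rhat"] > 1.5
        assert rep.iloc[0]["flagged"]

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            diagnostics_report(self._draws_from(rng.standard_normal((1, 1000))))
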