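"""Gibbs sampler correctness, summaries, and spec validation."""

import networkx as nx
import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

import saeprev as sp
from tests.conftest import make_directs


def line_graph(ids):
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(zip(ids[:-1], ids[1:]))
    return g


class TestSpecValidation:
    def test_burn_in_bounds(self):
        with pytest.raises(ValueError):
            sp.SmoothingSpec(iterations=100, burn_in=100)

    def test_level_bounds(self):
        with pytest.raises(ValueError):
            sp.SmoothingSpec(level=1.0)

    def test_structure_names(self):
        with pytest.raises(ValueError):
            sp.SmoothingSpec(effect_structure="car")


def test_single_area_posterior_tracks_data():
    """One likelihood term, iid structure, vague prior: E[eta] ~= theta_hat."""
    d = make_directs([0.8], [0.04])
    spec = sp.SmoothingSpec(effect_structure="iid_only", iterations=6000,
                            burn_in=1000, thinning=1)
    fit = sp.fit_smoothing_model(d, None, spec, seed=1)
    eta = fit.eta_draws[:, 0]
    mc_se = eta.std() / np.sqrt(fit.n_draws / 20)  # conservative ESS deflation
    assert abs(eta.mean() - 0.8) < 3 * mc_se


def test_two_area_posterior_matches_conjugate_closed_form():
    """iid structure with fixed tau_v: posterior mean and sd of each eta_i
    have a normal-normal closed form after integrating the flat mu."""
    theta = np.array([-0.58, 0.0])
    V = np.array([0.04, 0.08])
    tau = 4.0
    d = make_directs(theta, V)
    spec = sp.SmoothingSpec(effect_structure="iid_only", iterations=40_000,
                            burn_in=4000, thinning=1, fixed_tau_v=tau)
    fit = sp.fit_smoothing_model(d, None, spec, seed=3)
    eta = fit.eta_draws
    w = 1.0 / (V + 1.0 / tau)
    mu_hat, mu_var = (w @ theta) / w.sum(), 1.0 / w.sum()
    P = 1.0 / V
    shrink = tau / (P + tau)
    mean_cf = (P * theta + tau * mu_hat) / (P + tau)
    var_cf = 1.0 / (P + tau) + shrink**2 * mu_var
    mc_se = eta.std(0) / np.sqrt(fit.n_draws / 25)
    assert np.all(np.abs(eta.mean(0) - mean_cf) < 3 * mc_se)
    assert np.allclose(eta.var(0), var_cf, rtol=0.1)


def test_draw_invariants(small_geo, small_survey):
    w = small_survey["base_weight"].to_numpy()
    d = sp.empirical_logit(
        sp.direct_estimate(small_survey, w, "tract", areas=small_geo.tract_ids)
    )
    spec = sp.SmoothingSpec(iterations=600, burn_in=200, thinning=2)
    fit = sp.fit_smoothing_model(d, small_geo.tract_graph(), spec, seed=5)
    assert fit.n_draws == (600 - 200) // 2
    assert np.allclose(fit.u_draws.sum(axis=1), 0.0, atol=1e-6)
    assert (fit.tau_u_draws > 0).all() and (fit.tau_v_draws > 0).all()
    est = fit.estimates(level=0.9)
    assert ((est["lower"] > 0) & (est["upper"] < 1)).all()
    assert (est["lower"] <= est["median"]).all() and (est["median"] <= est["upper"]).all()


def test_degenerate_areas_predicted_from_prior(small_geo, small_survey):
    """Areas with no data still get estimates strictly inside (0,1)."""
    w = small_survey["base_weight"].to_numpy()
    keep = small_survey["tract"] != small_geo.tract_ids[0]  # empty one tract
    d = sp.empirical_logit(
        sp.direct_estimate(small_survey[keep], w[keep.to_numpy()], "tract",
                           areas=small_geo.tract_ids)
    )
    assert d.iloc[0]["degenerate"]
    spec = sp.SmoothingSpec(iterations=800, burn_in=300, thinning=1)
    fit = sp.fit_smoothing_model(d, small_geo.tract_graph(), spec, seed=6)
    est = fit.estimates()
    row = est.iloc[0]
    assert 0 < row["lower"] <= row["median"] <= row["upper"] < 1
    # prediction-only interval is wider than a typical data-backed one
    assert row["ci_half_width"] > est["ci_half_width"].median()


def test_seeded_runs_reproducible(small_geo, small_survey):
    w = small_survey["base_weight"].to_numpy()
    d = sp.empirical_logit(sp.direct_estimate(small_survey, w, "tract",
                                              areas=small_geo.tract_ids))
    spec = sp.SmoothingSpec(iterations=400, burn_in=100, thinning=1)
    f1 = sp.fit_smoothing_model(d, small_geo.tract_graph(), spec, seed=8)
    f2 = sp.fit_smoothing_model(d, small_geo.tract_graph(), spec, seed=8)
    assert np.array_equal(f1.mu_draws, f2.mu_draws)
    assert np.array_equal(f1.u_draws, f2.u_draws)


def test_smoothing_beats_direct_on_synthetic_county():
    """Parameter recovery: posterior medians closer to truth than raw
    direct estimates on a 100-tract county."""
    geo = sp.generate_geography(100, 14, 8, seed=41)
    truth = sp.simulate_truth(geo, seed=42)
    resp = sp.simulate_survey(truth, geo, 3000, seed=43)
    w = resp["base_weight"].to_numpy()
    d = sp.empirical_logit(sp.direct_estimate(resp, w, "tract", areas=geo.tract_ids))
    spec = sp.SmoothingSpec(iterations=1500, burn_in=500, thinning=2)
    fit = sp.fit_smoothing_model(d, geo.tract_graph(), spec, seed=44)
    med = fit.estimates().set_index("area_id")["median"].loc[geo.tract_ids].to_numpy()
    p_hat = d.set_index("area_id")["p_hat"].loc[geo.tract_ids].to_numpy()
    ok = np.isfinite(p_hat)
    rmse_direct = np.sqrt(np.mean((p_hat[ok] - truth.p_true[ok]) ** 2))
    rmse_smooth = np.sqrt(np.mean((med - truth.p_true) ** 2))
    assert rmse_smooth < rmse_direct


class TestSummaries:
    def _manual_fit(self, draws):
        """Results object with prescribed single-area mu draws."""
        d = make_directs([0.0], [1.0])
        model = sp.PrevalenceSmoother(
            d, None, sp.SmoothingSpec(effect_structure="iid_only",
                                      iterations=len(draws) + 1, burn_in=0, thinning=1)
        )
        return sp.SmoothingResults(
            model=model, spec=model.spec, area_ids=["a0"],
            mu_draws=np.asarray(draws, float), u_draws=None,
            v_draws=np.zeros((len(draws), 1)), tau_u_draws=None,
            tau_v_draws=np.ones(len(draws)),
        )

    def test_symmetric_logit_draws_give_median_half(self):
        z = np.linspace(-2, 2, 401)
        fit = self._manual_fit(z)
        assert fit.estimates(0.8).iloc[0]["median"] == pytest.approx(0.5)

    def test_wider_level_nests_narrower(self):
        rng = np.random.default_rng(0)
        fit = self._manual_fit(rng.standard_normal(2000))
        e80 = fit.estimates(0.80).iloc[0]
        e95 = fit.estimates(0.95).iloc[0]
        assert e95["lower"] < e80["lower"] and e95["upper"] > e80["upper"]

    def test_endpoints_match_normal_quantiles_through_inverse_logit(self):
        rng = np.random.default_rng(1)
        mu, sd = -2.197, 0.25
        fit = self._manual_fit(mu + sd * rng.standard_normal(40_000))
        est = fit.estimates(0.90).iloc[0]
        lo = expit(mu + sd * norm.ppf(0.05))
        hi = expit(mu + sd * norm.ppf(0.95))
        assert est["lower"] == pytest.approx(lo, rel=0.02)
        assert est["upper"] == pytest.approx(hi, rel=0.02)

    def test_too_few_draws_refused(self):
        fit = self._manual_fit(np.zeros(50))
        with pytest.raises(ValueError, match="100"):
            fit.estimates(0.9)


class TestInputValidation:
    def test_nonpositive_variance_rejected(self):
        d = make_directs([0.0, 0.5], [0.1, 0.0])
        with pytest.raises(ValueError, match="var_theta"):
            sp.PrevalenceSmoother(d, line_graph(["a0", "a1"]), sp.SmoothingSpec())

    def test_disconnected_adjacency_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(["a0", "a1", "a2"])
        g.add_edge("a0", "a1")
        d = make_directs([0.0, 0.1, 0.2], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="connected"):
            sp.PrevalenceSmoother(d, g, sp.SmoothingSpec())

    def test_missing_adjacency_for_icar(self):
        d = make_directs([0.0, 0.1], [0.1, 0.1])
        with pytest.raises(ValueError, match="adjacency"):
            sp.PrevalenceSmoother(d, None, sp.SmoothingSpec())
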