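"""Crosswalk allocation, multiple-imputation pooling, HRA assignment."""

import numpy as np
import pandas as pd
import pytest

import saeprev as sp


def make_missing(n, zip_id="z1"):
    return pd.DataFrame(
        {"id": range(n), "zip": zip_id, "tract": np.nan, "y": 0, "base_weight": 1.0}
    )


class TestAllocateMissing:
    def test_single_tract_zip_degenerate(self):
        cw = pd.DataFrame({"zip": ["z1"], "tract": ["t1"], "res_ratio": [1.0]})
        out = sp.allocate_missing(make_missing(20), cw, seed=1)
        assert (out["tract"] == "t1").all()

    def test_three_way_split_matches_crosswalk_ratios(self):
        """10,000 respondents over shares (0.705, 0.208, 0.087)."""
        shares = np.array([0.705, 0.208, 0.087])
        cw = pd.DataFrame(
            {"zip": "z1", "tract": ["east", "north", "central"], "res_ratio": shares}
        )
        out = sp.allocate_missing(make_missing(10_000), cw, seed=2)
        frac = out["tract"].value_counts(normalize=True)
        for t, s in zip(["east", "north", "central"], shares):
            se = np.sqrt(s * (1 - s) / 10_000)
            assert abs(frac[t] - s) < 3 * se

    def test_determinism_and_seed_sensitivity(self):
        cw = pd.DataFrame({"zip": "z1", "tract": ["a", "b"], "res_ratio": [0.6, 0.4]})
        r = make_missing(500)
        o1 = sp.allocate_missing(r, cw, seed=3)
        o2 = sp.allocate_missing(r, cw, seed=3)
        o3 = sp.allocate_missing(r, cw, seed=4)
        assert o1["tract"].equals(o2["tract"])
        assert not o1["tract"].equals(o3["tract"])

    def test_observed_tracts_never_moved(self, small_geo, small_truth):
        resp = sp.simulate_survey(small_truth, small_geo, 2000, seed=5)
        miss = sp.apply_missingness(resp, sp.calibrate_missingness(small_geo), seed=6)
        out = sp.allocate_missing(miss, small_geo.crosswalk, seed=7)
        observed = miss["tract"].notna()
        assert out.loc[observed, "tract"].equals(miss.loc[observed, "tract"])
        assert out["tract"].notna().all()
        assert out.drop(columns="tract").equals(miss.drop(columns="tract"))

    def test_unknown_zip_listed(self):
        cw = pd.DataFrame({"zip": ["z1"], "tract": ["t1"], "res_ratio": [1.0]})
        bad = make_missing(3, zip_id="z9")
        with pytest.raises(ValueError, match="z9"):
            sp.allocate_missing(bad, cw, seed=0)

    def test_allocation_frequencies_pass_goodness_of_fit(self):
        """Chi-square GOF vs crosswalk ratios not rejected at alpha=0.01."""
        from scipy.stats import chisquare

        shares = np.array([0.5, 0.3, 0.2])
        cw = pd.DataFrame({"zip": "z1", "tract": ["a", "b", "c"], "res_ratio": shares})
        rejections = 0
        for seed in range(20):
            out = sp.allocate_missing(make_missing(10_000), cw, seed=seed)
            counts = out["tract"].value_counts().reindex(["a", "b", "c"]).fillna(0)
            _, p = chisquare(counts, 10_000 * shares)
            rejections += p < 0.01
        assert rejections <= 1


@pytest.fixture(scope="module")
def mi_setup(small_geo, small_truth):
    resp = sp.simulate_survey(small_truth, small_geo, 3000, seed=21)
    miss = sp.apply_missingness(resp, sp.calibrate_missingness(small_geo), seed=22)
    spec = sp.SmoothingSpec(iterations=600, burn_in=200, thinning=2)
    return resp, miss, spec


class TestRunMiSmoothing:
    def test_m1_pooling_is_identity(self, small_geo, mi_setup):
        _, miss, spec = mi_setup
        w = miss["base_weight"].to_numpy()
        run = sp.run_mi_smoothing(miss, w, small_geo, spec=spec, M=1, seed=31)
        pooled = sp.pool_estimates(run, level=0.9)
        single = run.fits[0].estimates(level=0.9)
        for col in ("median", "lower", "upper"):
            assert np.allclose(pooled[col], single[col])

    def test_no_missingness_gives_identical_imputations(self, small_geo, mi_setup):
        resp, _, spec = mi_setup  # resp has complete geocodes
        w = resp["base_weight"].to_numpy()
        run = sp.run_mi_smoothing(resp, w, small_geo, spec=spec, M=3, seed=32)
        for tab in run.completed[1:]:
            assert tab["tract"].equals(run.completed[0]["tract"])
        assert len(set(run.sub_seeds)) == 3

    def test_pooled_variance_dominates_within_variance(self, small_geo, mi_setup):
        """Law of total variance on the draw mixture, area by area."""
        _, miss, spec = mi_setup
        w = miss["base_weight"].to_numpy()
        run = sp.run_mi_smoothing(miss, w, small_geo, spec=spec, M=4, seed=33)
        within = np.mean([f.prevalence_draws.var(axis=0) for f in run.fits], axis=0)
        pooled = np.concatenate([f.prevalence_draws for f in run.fits]).var(axis=0)
        assert np.all(pooled >= within - 1e-12)


class TestPoolEstimates:
    def _run_from(self, fits):
        comp = [pd.DataFrame({"tract": ["t"]})] * len(fits)
        return sp.ImputationRun(M=len(fits), completed=comp, fits=fits,
                                sub_seeds=list(range(len(fits))))

    def test_identical_posteriors_pool_to_component(self, small_geo, mi_setup):
        _, miss, spec = mi_setup
        w = miss["base_weight"].to_numpy()
        comp = sp.allocate_missing(miss, small_geo.crosswalk, seed=40)
        d = sp.empirical_logit(sp.direct_estimate(comp, w, "tract",
                                                  areas=small_geo.tract_ids))
        fit = sp.fit_smoothing_model(d, small_geo.tract_graph(), spec, seed=41)
        pooled = sp.pool_estimates(self._run_from([fit, fit]), level=0.9)
        single = fit.estimates(0.9)
        for col in ("median", "lower", "upper"):
            assert np.allclose(pooled[col], single[col])

    def test_shifted_posteriors_widen_interval(self, small_geo, mi_setup):
        _, miss, spec = mi_setup
        w = miss["base_weight"].to_numpy()
        fits = []
        for seed in (50, 51):
            comp = sp.allocate_missing(miss, small_geo.crosswalk, seed=seed)
            d = sp.empirical_logit(sp.direct_estimate(comp, w, "tract",
                                                      areas=small_geo.tract_ids))
            fits.append(sp.fit_smoothing_model(d, small_geo.tract_graph(), spec,
                                               seed=seed))
        pooled = sp.pool_estimates(self._run_from(fits), level=0.9)
        hw = [f.estimates(0.9)["ci_half_width"].to_numpy() for f in fits]
        narrowest = np.minimum(hw[0], hw[1])
        # pooled intervals never materially narrower than the narrowest component
        assert np.all(pooled["ci_half_width"].to_numpy() > narrowest - 0.01)


class TestAssignHra:
    def _geo(self):
        return sp.generate_geography(12, 3, 3, seed=61)

    def test_dominant_share_assigned_deterministically(self):
        geo = self._geo()
        hs = pd.DataFrame({"zip": ["z1", "z1"], "hra": ["h1", "h2"],
                           "pop_share": [0.96, 0.04]})
        geo2 = sp.GeographyModel(
            tract_ids=geo.tract_ids, zip_ids=geo.zip_ids + ["z1"],
            hra_ids=geo.hra_ids + ["h1", "h2"], edges=geo.edges,
            crosswalk=geo.crosswalk, hra_share=pd.concat([geo.hra_share, hs]),
            tract_to_hra=geo.tract_to_hra,
        )
        resp = make_missing(200, zip_id="z1")
        out = sp.assign_hra(resp, geo2, threshold=0.95, seed=1)
        assert (out["hra"] == "h1").all()

    def test_split_zip_follows_population_shares(self):
        geo = self._geo()
        shares = np.array([0.705, 0.208, 0.087])
        hs = pd.DataFrame({"zip": "zx", "hra": ["e", "n", "c"], "pop_share": shares})
        geo2 = sp.GeographyModel(
            tract_ids=geo.tract_ids, zip_ids=geo.zip_ids + ["zx"],
            hra_ids=geo.hra_ids + ["e", "n", "c"], edges=geo.edges,
            crosswalk=geo.crosswalk, hra_share=pd.concat([geo.hra_share, hs]),
            tract_to_hra=geo.tract_to_hra,
        )
        out = sp.assign_hra(make_missing(10_000, zip_id="zx"), geo2,
                            threshold=0.95, seed=2)
        frac = out["hra"].value_counts(normalize=True)
        for h, s in zip(["e", "n", "c"], shares):
            se = np.sqrt(s * (1 - s) / 10_000)
            assert abs(frac[h] - s) < 3 * se

    def test_geocoded_respondents_take_tract_hra(self, small_geo, small_truth):
        resp = sp.simulate_survey(small_truth, small_geo, 500, seed=3)
        out = sp.assign_hra(resp, small_geo, seed=4)
        expected = resp["tract"].map(small_geo.tract_to_hra)
        assert out["hra"].equals(expected)

    def test_threshold_bounds(self, small_geo, small_truth):
        resp = sp.simulate_survey(small_truth, small_geo, 10, seed=5)
        with pytest.raises(ValueError, match="threshold"):
            sp.assign_hra(resp, small_geo, threshold=0.4, seed=6)
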