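"""Rate-course GLM fitting, DEG calling and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import growthmodulon as gm
from growthmodulon.de import (
    DEFAULT_LFC_CUTOFFS,
    RateCourseDE,
    benjamini_hochberg,
    call_degs,
    evaluate_log2fc,
    fit_gene_profile,
    fit_rate_course,
)

MU15 = np.repeat([0.0, 0.1, 0.2, 0.3, 0.4], 3)
SF15 = np.ones(15)


class TestBenjaminiHochberg:
    def test_equal_pvalues_unchanged(self):
        assert np.allclose(benjamini_hochberg([0.2] * 5), 0.2)

    def test_hand_computed_step_up(self):
        got = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_second_hand_example(self):
        # sorted p (0.005, 0.04, 0.2): adj = (0.015, 0.06, 0.2)
        got = benjamini_hochberg([0.2, 0.005, 0.04])
        assert np.allclose(got, [0.2, 0.015, 0.06])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.031])[0] == pytest.approx(0.031)

    def test_invalid_p_rejected(self):
        for bad in ([1.5], [-0.1], [np.nan]):
            with pytest.raises(ValueError):
                benjamini_hochberg(bad)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30)
    )
    def test_dominates_raw_and_readjusting_only_inflates(self, ps):
        # BH is not idempotent (e.g. [0.1, 1.0] -> [0.2, 1.0] -> [0.4, 1.0]);
        # the correct invariants are dominance, the cap at 1, and that a
        # second adjustment can only move values up
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        assert np.all(benjamini_hochberg(adj) >= adj - 1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    def test_monotone_in_order_statistics(self, ps):
        order = np.argsort(ps)
        adj = benjamini_hochberg(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)


def _simulate_gene(rng, template, mu, dispersion, base=500.0):
    m = base * np.exp2(np.interp(mu, [0.0, 0.1, 0.2, 0.3, 0.4], template))
    if dispersion > 0:
        lam = rng.gamma(1 / dispersion, m * dispersion)
        return rng.poisson(lam)
    return rng.poisson(m)


class TestFitRateCourse:
    def test_flat_gene_has_null_fit(self, rng):
        y = rng.poisson(300, size=15)
        counts = pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(15)])
        res = fit_rate_course(counts, MU15, SF15)
        row = res.iloc[0]
        assert row["p_value"] > 0.05
        assert row["max_abs_log2fc"] < 0.3

    def test_all_zero_gene_flagged(self, rng):
        counts = pd.DataFrame(
            np.vstack([rng.poisson(100, 15), np.zeros(15, dtype=int)]),
            index=["g1", "g0"], columns=[f"s{i}" for i in range(15)],
        )
        res = fit_rate_course(counts, MU15, SF15)
        assert bool(res.loc["g0", "all_zero"])
        assert res.loc["g0", "p_value"] == 1.0
        assert res.loc["g0", "max_abs_log2fc"] == 0.0

    def test_log2fc_anchored_at_reference(self, rng):
        tmpl = gm.make_profile_templates([0, 0.1, 0.2, 0.3, 0.4], 1.5)[1]
        y = _simulate_gene(rng, tmpl, MU15, 0.02)
        counts = pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(15)])
        res = fit_rate_course(counts, MU15, SF15)
        assert res.iloc[0]["log2fc_0.4"] == 0.0

    def test_deviance_matches_statsmodels_poisson_oracle(self, rng):
        """Dual route: our batched Poisson IRLS against statsmodels GLM on a
        small fixed dataset (deviance difference = 2*(ll_full - ll_null))."""
        y = _simulate_gene(
            rng, gm.make_profile_templates([0, .1, .2, .3, .4], 1.2)[4], MU15, 0.0,
            base=80.0,
        )
        sf = np.exp(rng.uniform(-0.3, 0.3, 15))
        counts = pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(15)])
        res = fit_rate_course(counts, MU15, sf, family="poisson")
        X = np.column_stack([MU15**k for k in range(4)])
        full = sm.GLM(
            y, X, family=sm.families.Poisson(), offset=np.log(sf)
        ).fit()
        null = sm.GLM(
            y, np.ones((15, 1)), family=sm.families.Poisson(), offset=np.log(sf)
        ).fit()
        # coefficients agree
        beta = res.iloc[0][["beta0", "beta1", "beta2", "beta3"]].to_numpy(float)
        assert np.allclose(beta, full.params, rtol=1e-5, atol=1e-6)
        # independent likelihood evaluation of the tested statistic
        lrt_oracle = 2 * (full.llf - null.llf)
        x2 = float(((y - full.mu) ** 2 / full.mu).sum())
        scale = max(1.0, x2 / 11)
        f_oracle = (lrt_oracle / 3) / scale
        from scipy import stats as sps
        assert res.iloc[0]["p_value"] == pytest.approx(
            sps.f.sf(f_oracle, 3, 11), rel=1e-4
        )

    def test_nb_coefficients_match_statsmodels_at_fixed_dispersion(self, rng):
        y = _simulate_gene(
            rng, gm.make_profile_templates([0, .1, .2, .3, .4], 1.5)[1], MU15, 0.05
        )
        counts = pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(15)])
        res = fit_rate_course(counts, MU15, SF15)
        phi = res.iloc[0]["dispersion"]
        assert phi > 0
        X = np.column_stack([MU15**k for k in range(4)])
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=phi)
        ).fit()
        beta = res.iloc[0][["beta0", "beta1", "beta2", "beta3"]].to_numpy(float)
        assert np.allclose(beta, ref.params, rtol=1e-4, atol=1e-4)

    def test_planted_cluster1_gene_detected_in_90pct(self):
        """Monte-Carlo power: amplitude 1.5, dispersion 0.05, 3 replicates per
        rate point; detection with p_adj < 0.05 and max|log2FC| in [1, 2]."""
        rng = np.random.default_rng(1234)
        tmpl = gm.make_profile_templates([0, 0.1, 0.2, 0.3, 0.4], 1.5)[1]
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            y = _simulate_gene(rng, tmpl, MU15, 0.05)
            fit = fit_gene_profile(y, MU15, SF15, gene_id="g")
            if fit.p_adjusted < 0.05 and 1.0 <= fit.max_abs_log2fc <= 2.0:
                hits += 1
        assert hits / n_sim >= 0.9

    def test_insufficient_design_rejected(self, rng):
        counts = pd.DataFrame([rng.poisson(100, 6)], index=["g"])
        with pytest.raises(ValueError):
            fit_rate_course(counts, np.repeat([0.1, 0.4], 3), np.ones(6))

    def test_per_gene_dispersion_mode_runs(self, rng):
        y = np.vstack([_simulate_gene(rng, np.zeros(5), MU15, 0.1)
                       for _ in range(5)])
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(15)])
        res = fit_rate_course(counts, MU15, SF15, dispersion="per-gene")
        assert (res["p_value"] > 0).all()
        with pytest.raises(ValueError):
            fit_rate_course(counts, MU15, SF15, dispersion="bogus")


class TestCallDegs:
    def test_cutoff_and_alpha_are_both_required(self, small_fits):
        fits, _ = small_fits
        f = fits["phosphate"]
        degs = call_degs(f, alpha=0.05, log2fc_cutoff=0.73)
        for g in degs.genes:
            assert f.loc[g, "p_adjusted"] < 0.05
            assert f.loc[g, "max_abs_log2fc"] >= 0.73

    def test_hopeless_pvalues_give_empty_set(self):
        f = pd.DataFrame(
            {"p_adjusted": [0.5, 0.9], "max_abs_log2fc": [3.0, 3.0]},
            index=["a", "b"],
        )
        assert call_degs(f, 0.05, 0.73).genes == set()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            call_degs(pd.DataFrame(), 0.05, 0.73)

    def test_shipped_condition_cutoffs(self):
        assert DEFAULT_LFC_CUTOFFS == {
            "phosphate": 0.73, "nitrogen": 0.73, "carbon": 0.6
        }


class TestRateCourseDEEstimator:
    def test_sklearn_surface(self, small_sim):
        counts, meta, truth = small_sim
        sel = meta["condition"] == "phosphate"
        ids = meta.loc[sel, "sample_id"].tolist()
        X = counts[ids].T  # samples x genes
        est = RateCourseDE(lfc_cutoff=0.73).fit(
            X, meta.loc[sel, "mu"].to_numpy(float)
        )
        assert est.coef_.shape == (counts.shape[0], 4)
        assert est.log2fc_.shape == (counts.shape[0], 5)
        assert est.reference_mu_ == 0.4
        # predict re-evaluates the fitted profiles
        assert np.allclose(est.predict(est.mu_grid_), est.log2fc_, atol=1e-9)
        # DEG indices match a manual filter
        manual = np.flatnonzero(
            (est.p_adjusted_ < 0.05) & (est.max_abs_log2fc_ >= 0.73)
        )
        assert np.array_equal(est.degs_, manual)
        from sklearn.base import clone
        clone(est)

    def test_profilefit_container(self, rng):
        y = rng.poisson(200, 15)
        fit = fit_gene_profile(y, MU15, SF15, gene_id="cg0001",
                               condition="phosphate")
        assert fit.gene_id == "cg0001"
        assert fit.p_adjusted == fit.p_value  # single-gene BH is identity
        assert fit.log2fc.loc[0.4] == 0.0
        assert fit.max_abs_log2fc == pytest.approx(
            np.abs(fit.log2fc).max()
        )


def test_evaluate_log2fc_matches_direct_polynomial():
    beta = np.array([1.0, -2.0, 3.0, 0.5])
    grid = np.array([0.0, 0.2, 0.4])
    got = evaluate_log2fc(beta, grid, 0.4)

    def poly(x):
        return beta[0] + beta[1] * x + beta[2] * x**2 + beta[3] * x**3

    expected = (np.array([poly(x) for x in grid]) - poly(0.4)) / np.log(2)
    assert np.allclose(got, expected)
    assert got[-1] == 0.0
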