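"""Hierarchical Bayes sampler: degenerate cases, quadrature oracle,
diagnostics, variance component, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import saeprev as sp
from saeprev.hb import (HBModelSpec, PosteriorDraws, effective_sample_size,
                        split_rhat)


def _draws_from_prevalence(P, sigma=None):
    """Wrap raw prevalence draws (n, areas) in a PosteriorDraws shell."""
    P = np.asarray(P, dtype=float)
    n, a = P.shape
    areas = [f"area_{i}" for i in range(a)]
    return PosteriorDraws(
        beta=np.zeros((1, n, 1)), v=np.zeros((1, n, a)),
        sigma_v=np.full((1, n), 0.0 if sigma is None else sigma),
        area_prevalence=P[None], beta_names=["intercept"], areas=areas,
        n_by_area=pd.Series(100, index=areas))


def test_spec_validation():
    with pytest.raises(ValueError, match="n_burnin"):
        HBModelSpec(n_iter=100, n_burnin=100)
    with pytest.raises(ValueError, match="prior"):
        HBModelSpec(sigma_prior="cauchy")


def test_single_area_collapses_to_binomial():
    """Intercept-only, sigma_v fixed at 0, one area: the posterior mean of
    prevalence must match the sample proportion up to Monte-Carlo error."""
    census = pd.DataFrame({"area_id": ["a"], "cell_id": ["all"], "count": [1000]})
    k, n = 27, 90
    survey = pd.DataFrame({"unit_id": range(n), "area_id": "a", "cell_id": "all",
                           "y": [1] * k + [0] * (n - k), "w": 1.0})
    model = sp.HierarchicalBayes(census, factors={}, sigma_fixed=0.0,
                                 n_iter=8_000, n_burnin=1_000, seed=2).fit(survey)
    P = model.draws_.area_prevalence_draws[:, 0]
    mc_se = P.std(ddof=1) / np.sqrt(effective_sample_size(P[None]))
    # with a flat-ish prior the posterior mean is ~ (k + eps)/(n + eps')
    assert abs(P.mean() - k / n) < 2 * mc_se + 0.01
    assert ((P > 0) & (P < 1)).all()


def test_posterior_matches_grid_quadrature_oracle(two_area_toy):
    """MCMC posterior means agree with deterministic 2-D quadrature over
    (intercept, v_a, v_b) within 2% on the toy problem."""
    census, survey = two_area_toy
    SIG, TAU = 0.7, 10.0
    data = {"area_a": (40, 12), "area_b": (35, 18)}

    b0 = np.linspace(-6, 4, 401)
    vg = np.linspace(-4, 4, 401)
    lp_v = -0.5 * (vg / SIG) ** 2

    def area_terms(n, k):
        eta = b0[:, None] + vg[None, :]
        ll = k * eta - n * np.logaddexp(0, eta) + lp_v
        e = np.exp(ll - ll.max())
        return e.sum(axis=1), (expit(eta) * e).sum(axis=1)

    Za, Ma = area_terms(*data["area_a"])
    Zb, Mb = area_terms(*data["area_b"])
    wb0 = np.exp(-0.5 * (b0 / TAU) ** 2) * Za * Zb
    wb0 /= wb0.sum()
    oracle = {"area_a": float((wb0 * Ma / Za).sum()),
              "area_b": float((wb0 * Mb / Zb).sum())}

    model = sp.HierarchicalBayes(census, factors={}, sigma_fixed=SIG,
                                 prior_beta_sd=TAU, n_iter=40_000,
                                 n_burnin=4_000, seed=9).fit(survey)
    P = model.draws_.area_prevalence_draws
    for i, area in enumerate(model.draws_.areas):
        assert P[:, i].mean() == pytest.approx(oracle[area], rel=0.02)


def test_summary_degenerate_draws():
    s = sp.summarize_posterior(_draws_from_prevalence(np.full((200, 2), 0.3)))
    assert np.allclose(s["mse"], 0.0, atol=1e-16)
    assert (s["ci_high"] - s["ci_low"] == 0).all()
    assert np.allclose(s["estimate"], 0.3)


def test_summary_normal_draws_analytic_quantiles():
    rng = np.random.default_rng(1)
    x = np.clip(rng.normal(0.25, 0.02, size=(20_000, 1)), 1e-6, 1 - 1e-6)
    s = sp.summarize_posterior(_draws_from_prevalence(x))
    assert s["ci_low"].iloc[0] == pytest.approx(0.25 - 1.96 * 0.02, abs=0.002)
    assert s["ci_high"].iloc[0] == pytest.approx(0.25 + 1.96 * 0.02, abs=0.002)
    assert s["mse"].iloc[0] == pytest.approx(0.0004, rel=0.05)


def test_summary_requires_min_draws():
    with pytest.raises(ValueError, match="draws"):
        sp.summarize_posterior(_draws_from_prevalence(np.full((50, 1), 0.2)))


def test_diagnostics_iid_and_constant_and_ar1():
    rng = np.random.default_rng(3)
    iid = rng.normal(size=(2, 4_000))
    assert 0.99 <= split_rhat(iid) <= 1.05
    assert effective_sample_size(iid) > 0.5 * iid.size

    const = np.full((1, 1_000), 2.0)
    assert effective_sample_size(const) == 1.0

    rho = 0.5
    n = 40_000
    eps = rng.normal(size=n)
    x = np.empty(n)
    x[0] = eps[0]
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    ratio = effective_sample_size(x[None]) / n
    assert ratio == pytest.approx((1 - rho) / (1 + rho), rel=0.2)


def test_diagnostics_report_flags_constant_parameter():
    draws = _draws_from_prevalence(np.full((500, 1), 0.4))
    rep = sp.convergence_diagnostics(draws)
    row = rep.set_index("parameter").loc["v[area_0]"]
    assert "degenerate ESS" in row["warnings"]


def test_variance_component_flag_by_truth(census31, sizes31):
    """sigma_v = 0.5 data supports the random effect; sigma_v = 0 data does
    not (in most replicates)."""
    truth = sp.generate_truth(census31, sigma_v=0.5, seed=77)
    sv = sp.draw_survey(census31, truth, sizes31, seed=77)
    m = sp.HierarchicalBayes(census31, n_iter=2_000, n_burnin=500,
                             seed=77).fit(sv)
    vc = sp.variance_component_summary(m.draws_)
    assert vc["supported"]

    not_sup = 0
    reps = 5
    for rep in range(reps):
        t0 = sp.generate_truth(census31, sigma_v=0.0, seed=500 + rep)
        s0 = sp.draw_survey(census31, t0, 250, seed=500 + rep)
        m0 = sp.HierarchicalBayes(census31, n_iter=6_000, n_burnin=1_000,
                                  seed=500 + rep).fit(s0)
        vc0 = sp.variance_component_summary(m0.draws_)
        not_sup += not vc0["supported"]
        # shrinkage: with no true area effects the posterior means of v
        # collapse toward the prior mean 0
        assert vc0["v_posterior_means"].abs().max() < 0.15
    assert not_sup >= 0.8 * reps


def test_shrinkage_toward_national_rate(survey31, census31):
    """Intercept-only HB estimates fall between each area's direct estimate
    and the national pooled rate in at least 90% of areas."""
    survey, _ = survey31
    hb = sp.HierarchicalBayes(census31, factors={}, n_iter=3_000,
                              n_burnin=500, seed=31).fit(survey)
    d = sp.DirectEstimator().fit(survey).estimates_.set_index("domain_id")["estimate"]
    nat = sp.weighted_prevalence(survey).estimate
    h = hb.estimates_.set_index("domain_id")["estimate"]
    between = ((h >= np.minimum(d, nat) - 1e-12) &
               (h <= np.maximum(d, nat) + 1e-12)).mean()
    assert between >= 0.9


def test_hb_intervals_narrower_for_small_areas(survey31, census31):
    survey, _ = survey31
    hb = sp.HierarchicalBayes(census31, n_iter=2_000, n_burnin=500,
                              seed=31).fit(survey)
    d = sp.DirectEstimator().fit(survey).estimates_.set_index("domain_id")
    h = hb.estimates_.set_index("domain_id")
    small = d.index[d["n"] < 420]
    frac = np.mean((h.loc[small, "ci_high"] - h.loc[small, "ci_low"]).to_numpy()
                   < (d.loc[small, "ci_high"] - d.loc[small, "ci_low"]).to_numpy())
    assert frac >= 0.9


def test_seed_reproducibility(small_survey, small_census):
    a = sp.fit_hb(small_survey, small_census,
                  HBModelSpec(n_iter=400, n_burnin=100, seed=5))
    b = sp.fit_hb(small_survey, small_census,
                  HBModelSpec(n_iter=400, n_burnin=100, seed=5))
    assert np.array_equal(a.beta, b.beta)
    assert np.array_equal(a.v, b.v)
    assert np.array_equal(a.area_prevalence, b.area_prevalence)


def test_two_chains_and_invgamma_prior(small_survey, small_census):
    m = sp.fit_hb(small_survey, small_census,
                  HBModelSpec(n_iter=600, n_burnin=200, n_chains=2,
                              sigma_prior="invgamma", seed=4))
    assert m.beta.shape[0] == 2
    rep = sp.convergence_diagnostics(m)
    assert rep.attrs["between_chain"]
    assert (m.sigma_v > 0).all()


def test_single_class_outcome_rejected(small_census):
    survey = pd.DataFrame({"unit_id": [0, 1], "area_id": "area_01",
                           "cell_id": "x", "y": [1, 1], "w": 1.0})
    with pytest.raises(ValueError, match="single class"):
        sp.fit_hb(survey, small_census, HBModelSpec(n_iter=200, n_burnin=50))
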