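"""Synthetic and composite estimators: hand arithmetic and structure."""

import numpy as np
import pandas as pd
import pytest

import saeprev as sp
from saeprev.direct import ESTIMATE_COLUMNS


def _est_frame(rows):
    """rows: (domain_id, estimate, mse)"""
    out = []
    for did, e, m in rows:
        half = 1.96 * np.sqrt(m)
        out.append({"domain_id": did, "method": "x", "estimate": e, "mse": m,
                    "ci_low": e - half, "ci_high": e + half,
                    "cv": np.sqrt(m) / e if e > 0 else np.nan, "n": 100})
    return pd.DataFrame(out)[ESTIMATE_COLUMNS]


@pytest.fixture()
def two_strata_world():
    """Two areas sharing two strata whose national rates are 0.1 and 0.3."""
    census = pd.DataFrame({
        "area_id": ["a1", "a1", "a2", "a2"],
        "cell_id": ["s1", "s2", "s1", "s2"],
        "grp": ["g1", "g2", "g1", "g2"],
        "count": [100, 300, 200, 200],
    })
    rows, uid = [], 0
    for grp, rate, n in (("g1", 0.1, 50), ("g2", 0.3, 50)):
        for j in range(n):
            rows.append((uid, "a1" if j % 2 else "a2", "s1" if grp == "g1" else "s2",
                         grp, int(j < rate * n), 1.0))
            uid += 1
    survey = pd.DataFrame(rows, columns=["unit_id", "area_id", "cell_id",
                                         "grp", "y", "w"])
    return census, survey


def test_single_stratum_gives_national_rate(small_survey, small_census):
    syn = sp.poststratified_synthetic(
        small_survey.assign(one="x"), small_census.assign(one="x"), ["one"])
    national = sp.weighted_prevalence(small_survey).estimate
    assert np.allclose(syn["estimate"], national)


def test_two_strata_hand_arithmetic(two_strata_world):
    census, survey = two_strata_world
    syn = sp.poststratified_synthetic(survey, census, ["grp"])
    by = syn.set_index("domain_id")["estimate"]
    # area a1: shares 100/400 and 300/400 of rates 0.1 / 0.3
    assert by["a1"] == pytest.approx(0.25 * 0.1 + 0.75 * 0.3)
    assert by["a2"] == pytest.approx(0.5 * 0.1 + 0.5 * 0.3)


def test_unsampled_stratum_is_an_error(two_strata_world):
    census, survey = two_strata_world
    with pytest.raises(ValueError, match="zero national sample"):
        sp.poststratified_synthetic(survey[survey["grp"] == "g1"], census,
                                    ["grp"])


@pytest.mark.parametrize(
    "syn,dire,vdir,expected",
    [
        (0.2, 0.2, 0.001, 0.0),                  # identical estimates
        (0.30, 0.20, 0.002, 0.008),              # hand arithmetic
        (0.21, 0.20, 0.002, 0.0),                # truncation boundary
    ],
)
def test_synthetic_mse_contrast(syn, dire, vdir, expected):
    out = sp.synthetic_mse(_est_frame([("a", syn, 0.0)]),
                           _est_frame([("a", dire, vdir)]))
    assert out["a"] == pytest.approx(expected)


def test_synthetic_mse_flags_missing_direct():
    out = sp.synthetic_mse(_est_frame([("a", 0.2, 0.0), ("b", 0.3, 0.0)]),
                           _est_frame([("a", 0.25, 0.001)]))
    assert out.attrs["flagged"] == ["b"]
    assert np.isnan(out["b"])


def test_synthetic_mse_smoothed_is_constant():
    syn = _est_frame([("a", 0.30, 0.0), ("b", 0.20, 0.0)])
    dire = _est_frame([("a", 0.20, 0.002), ("b", 0.25, 0.001)])
    out = sp.synthetic_mse(syn, dire, smoothed=True)
    expected = np.mean([(0.1) ** 2 - 0.002, (0.05) ** 2 - 0.001])
    assert np.allclose(out, expected)


def test_composite_limits_and_hand_arithmetic():
    dire = _est_frame([("a", 0.30, 0.004)])
    syn = _est_frame([("a", 0.20, 0.001)])
    comp, w = sp.composite(dire, syn)
    assert w.phi["a"] == pytest.approx(0.2)
    assert comp["estimate"].iloc[0] == pytest.approx(0.22)

    # mse_syn = 0 -> composite equals synthetic
    comp0, w0 = sp.composite(dire, _est_frame([("a", 0.20, 0.0)]))
    assert w0.phi["a"] == 0.0
    assert comp0["estimate"].iloc[0] == pytest.approx(0.20)

    # equal MSEs -> midpoint
    compm, wm = sp.composite(_est_frame([("a", 0.30, 0.002)]),
                             _est_frame([("a", 0.20, 0.002)]))
    assert wm.phi["a"] == pytest.approx(0.5)
    assert compm["estimate"].iloc[0] == pytest.approx(0.25)

    # degenerate 0/0 resolves to 1/2
    compz, wz = sp.composite(_est_frame([("a", 0.30, 0.0)]),
                             _est_frame([("a", 0.20, 0.0)]))
    assert wz.phi["a"] == 0.5


def test_composite_rejects_negative_mse():
    with pytest.raises(ValueError, match="non-negative"):
        sp.composite(_est_frame([("a", 0.3, 0.001)]),
                     _est_frame([("a", 0.2, 0.001)]),
                     mse_syn=pd.Series({"a": -0.1}))


def test_composite_convex_and_mse_bounded(small_survey, small_census):
    model = sp.CompositeEstimator(small_census, ["sex", "age"]).fit(small_survey)
    comp = model.estimates_.set_index("domain_id")
    dire = model.components_["direct"].set_index("domain_id")
    syn = model.components_["psyn"].set_index("domain_id")
    lo = np.minimum(dire["estimate"], syn["estimate"])
    hi = np.maximum(dire["estimate"], syn["estimate"])
    assert ((comp["estimate"] >= lo - 1e-12) &
            (comp["estimate"] <= hi + 1e-12)).all()
    assert (model.phi_.between(0, 1)).all()
    mse_syn = sp.synthetic_mse(syn.reset_index(), dire.reset_index())
    cap = np.maximum(dire["mse"], mse_syn)
    assert (comp["mse"] <= cap + 1e-15).all()


def test_sample_size_phi_variant(small_survey, small_census):
    model = sp.CompositeEstimator(small_census, ["sex"],
                                  phi_method="sample-size",
                                  delta=100.0).fit(small_survey)
    n = model.components_["direct"].set_index("domain_id")["n"]
    assert np.allclose(model.phi_, n / (n + 100.0))


def test_synthetic_range_compression(survey31, census31):
    """Heterogeneous areas: the synthetic estimator's between-area range is
    a small fraction of the direct range (borrowed strength, at the price of
    bias)."""
    survey, _ = survey31
    syn = sp.poststratified_synthetic(survey, census31,
                                      ["sex", "age", "residence"])
    dire = sp.DirectEstimator().fit(survey).estimates_
    assert np.ptp(syn["estimate"]) < 0.25 * np.ptp(dire["estimate"])


def test_synthetic_beats_direct_in_homogeneous_world():
    """When truth really is strata-only (no area effects), the synthetic
    estimator has smaller RMSE than the direct one in small areas."""
    census = sp.generate_census(n_areas=8, mean_area_pop=20_000,
                                area_pop_sigma=0.0, seed=41)
    truth = sp.generate_truth(census, sigma_v=0.0, seed=41)
    tp = truth.true_prevalence.sort_index().to_numpy()
    err_d, err_s = [], []
    for rep in range(40):
        sv = sp.draw_survey(census, truth, 60, seed=2_000 + rep)
        d = (sp.DirectEstimator().fit(sv).estimates_
             .set_index("domain_id")["estimate"].sort_index().to_numpy())
        s = (sp.poststratified_synthetic(sv, census, ["sex", "age", "residence"])
             .set_index("domain_id")["estimate"].sort_index().to_numpy())
        err_d.append(d - tp)
        err_s.append(s - tp)
    rmse_d = np.sqrt(np.mean(np.square(err_d), axis=0))
    rmse_s = np.sqrt(np.mean(np.square(err_s), axis=0))
    assert (rmse_s < rmse_d).all()
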