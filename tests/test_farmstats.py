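import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dairyshed as ds
from dairyshed import farmstats
from dairyshed.raster import GridSpec, RasterLayer

GRID = GridSpec(pixel_size=1000.0)


def L(vals):
    return RasterLayer(np.asarray(vals, dtype=float), grid=GRID)


def farms_at(points):
    return pd.DataFrame({"x": [p[0] for p in points], "y": [p[1] for p in points]})


# ---------------------------------------------------------------- neighbourhood stats
def test_uniform_layer_every_farm_gets_value():
    layer = L(np.full((10, 10), 3.7))
    farms = farms_at([(2500, -2500), (7500, -7500)])
    out = farmstats.neighbourhood_stats(farms, {"loss": layer}, radius_m=2500)
    np.testing.assert_allclose(out["loss"], 3.7)


def test_farm_with_no_valid_pixels_flagged_nan():
    vals = np.full((10, 10), -9999.0)
    vals[0, 0] = 5.0
    farms = farms_at([(8500, -8500)])
    out = farmstats.neighbourhood_stats(farms, {"loss": L(vals)}, radius_m=2000)
    assert np.isnan(out["loss"].iloc[0])
    assert out["n_forest_pixels"].iloc[0] == 0


def test_toy_mean_matches_hand_enumeration():
    vals = np.arange(1.0, 10.0).reshape(3, 3)
    farms = farms_at([(1500, -1500)])  # centre pixel
    out = farmstats.neighbourhood_stats(farms, {"loss": L(vals)}, radius_m=1100)
    # radius 1.1 km from centre: centre + 4 edge-adjacent pixels (2,4,5,6,8)
    assert out["loss"].iloc[0] == pytest.approx((2 + 4 + 5 + 6 + 8) / 5)


def test_geographic_crs_rejected():
    layer = RasterLayer(np.ones((2, 2)), grid=GridSpec(crs="EPSG:4326"))
    with pytest.raises(ValueError, match="projected"):
        farmstats.neighbourhood_stats(farms_at([(0, 0)]), {"x": layer})


# ---------------------------------------------------------------- correlations
def test_identical_columns_rho_one():
    survey = pd.DataFrame({"ind": np.arange(20.0)})
    nstats = pd.DataFrame({"lay": np.arange(20.0)})
    out = farmstats.indicator_correlations(survey, nstats, indicators=["ind"])
    assert out.rho.iloc[0] == pytest.approx(1.0)


def test_constant_column_reported_missing():
    survey = pd.DataFrame({"ind": np.ones(20)})
    nstats = pd.DataFrame({"lay": np.arange(20.0)})
    out = farmstats.indicator_correlations(survey, nstats, indicators=["ind"])
    assert np.isnan(out.rho.iloc[0])


def test_rho_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    y = x + rng.normal(size=100)
    survey1 = pd.DataFrame({"ind": x})
    survey2 = pd.DataFrame({"ind": np.exp(3 * x)})  # strictly monotone
    nstats = pd.DataFrame({"lay": y**3})
    r1 = farmstats.indicator_correlations(survey1, nstats, indicators=["ind"]).rho.iloc[0]
    r2 = farmstats.indicator_correlations(survey2, nstats, indicators=["ind"]).rho.iloc[0]
    assert r1 == pytest.approx(r2)


def test_independent_columns_null_distribution():
    """Monte-Carlo null: independent indicator and layer at n=216 give
    |rho| < 0.15 in at least 90% of replicates."""
    rng = np.random.default_rng(1)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        rho, _ = stats.spearmanr(rng.normal(size=216), rng.normal(size=216))
        hits += abs(rho) < 0.15
    assert hits >= 0.90 * n_rep


def test_collinear_indicators_flagged():
    rng = np.random.default_rng(2)
    a = rng.normal(size=50)
    survey = pd.DataFrame({"a": a, "b": a + 0.01 * rng.normal(size=50)})
    nstats = pd.DataFrame({"lay": rng.normal(size=50)})
    out = farmstats.indicator_correlations(survey, nstats, indicators=["a", "b"])
    assert (out[out.indicator == "a"].collinear_with == "b").all()


def test_survey_round_trip_recovers_targets(landscape):
    """Headline parameter-recovery test: survey generated on the landscape,
    zonal statistics of attributed loss within 5 km, Spearman correlations
    recover the requested targets within Monte-Carlo tolerance."""
    targets = {"n_cattle": 0.15, "n_improved_cattle": -0.37}
    att = ds.attribute_grazing_loss(
        landscape.net_c_loss, landscape.net_c_gain, landscape.forest_mask,
        landscape.plantation_mask, landscape.burn_mask, landscape.nrb, landscape.counties,
    )
    recovered = {k: [] for k in targets}
    for rep in range(10):
        survey = ds.generate_farm_survey(landscape, 216, effect_sizes=targets, seed=3000 + rep)
        ns = farmstats.neighbourhood_stats(survey, {"loss": att.c_loss_cattle}, 5000.0)
        out = farmstats.indicator_correlations(survey, ns, indicators=list(targets))
        for k in targets:
            recovered[k].append(out.set_index("indicator").loc[k, "rho"])
    for k, t in targets.items():
        assert np.mean(recovered[k]) == pytest.approx(t, abs=0.1)


# ---------------------------------------------------------------- Holm and letters
def test_holm_never_decreases_pvalues():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=10)
    adj = farmstats.holm_adjust(p)
    assert (adj >= p - 1e-15).all()
    assert (adj <= 1.0).all()


def test_holm_matches_hand_example():
    adj = farmstats.holm_adjust(np.array([0.01, 0.04, 0.03]))
    np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])


def test_compact_letter_display_one_distinct_group():
    sig = {("a", "b"): False, ("a", "c"): True, ("b", "c"): True}
    letters = farmstats.compact_letter_display(["a", "b", "c"], sig)
    assert letters["a"] == letters["b"]
    assert letters["c"] != letters["a"]


# ---------------------------------------------------------------- farm-type tests
def _typed_frame(shift_c=0.0, n=50, seed=0):
    rng = np.random.default_rng(seed)
    survey = pd.DataFrame({"farm_type": ["a"] * n + ["b"] * n + ["c"] * n})
    vals = np.concatenate(
        [rng.normal(0, 1, n), rng.normal(0, 1, n), rng.normal(shift_c, 1, n)]
    )
    return survey, pd.DataFrame({"loss": vals})


def test_identical_distributions_one_letter_group():
    survey, nstats = _typed_frame(shift_c=0.0, seed=4)
    out = farmstats.farm_type_tests(survey, nstats)
    assert not out.significant.any()
    assert (out.letters_a == out.letters_b).all()


def test_shifted_group_detected_with_power():
    """Two types shifted by 3 pooled SDs at n=50: adjusted p < .01 in at
    least 95% of replicates."""
    detected = 0
    n_rep = 20
    for rep in range(n_rep):
        survey, nstats = _typed_frame(shift_c=3.0, seed=100 + rep)
        out = farmstats.farm_type_tests(survey, nstats)
        sig = out[(out.type_a == "a") & (out.type_b == "c")]
        detected += (sig.p_holm < 0.01).all()
    assert detected >= 0.95 * n_rep


def test_letter_display_marks_distinct_group():
    survey, nstats = _typed_frame(shift_c=3.0, seed=5)
    out = farmstats.farm_type_tests(survey, nstats)
    letters = {r.type_a: r.letters_a for r in out.itertuples()}
    letters.update({r.type_b: r.letters_b for r in out.itertuples()})
    assert letters["a"] == letters["b"] != letters["c"]


def test_small_type_excluded():
    survey, nstats = _typed_frame(n=50, seed=6)
    survey.loc[survey.farm_type == "b", "farm_type"] = "a"
    survey.iloc[:3, 0] = "tiny"
    out = farmstats.farm_type_tests(survey, nstats)
    assert "tiny" not in set(out.type_a) | set(out.type_b)


def test_too_few_types_rejected():
    survey = pd.DataFrame({"farm_type": ["a"] * 10})
    nstats = pd.DataFrame({"loss": np.arange(10.0)})
    with pytest.raises(ValueError, match="at least 2"):
        farmstats.farm_type_tests(survey, nstats)
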