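import numpy as np
import pytest

from dairyshed import herd
from dairyshed.herd import (
    CowParams,
    Diet,
    EmissionFactors,
    Param,
    annual_concentrate,
    cow_emissions,
    emission_intensity,
    enteric_ch4,
    gross_energy_intake,
    lhs_uncertainty,
    lifetime_milk,
    manure_ch4,
    n2o_emissions,
    n_flows,
    vs_excretion,
)


def uniform_diet(kg, feed="pasture", **kw):
    return Diet(intakes={feed: kg}, **kw)


# ---------------------------------------------------------------- concentrate schedule
@pytest.mark.parametrize("kg_day, days, expected", [(3, 150, 450), (6, 150, 900), (0, 150, 0)])
def test_annual_concentrate(kg_day, days, expected):
    assert annual_concentrate(kg_day, days) == expected


def test_annual_concentrate_rejects_more_than_a_year():
    with pytest.raises(ValueError):
        annual_concentrate(3, 400)


# ---------------------------------------------------------------- energy intake
def test_gross_energy(feeds):
    assert gross_energy_intake(Diet(intakes={}), feeds) == 0.0
    assert gross_energy_intake(uniform_diet(1000.0), feeds) == pytest.approx(18450.0)
    # hand multiplication: baseline MRA dry-matter intake at uniform energy density
    assert gross_energy_intake(uniform_diet(3565.0), feeds) == pytest.approx(65774.25)


def test_gross_energy_missing_feed_named(feeds):
    with pytest.raises(KeyError, match="lucerne"):
        gross_energy_intake(Diet(intakes={"lucerne": 10.0}), feeds)


# ---------------------------------------------------------------- enteric CH4
def test_enteric_ch4_values():
    assert enteric_ch4(0.0, 0.065) == 0.0
    assert enteric_ch4(55.65, 0.1) == pytest.approx(0.1)
    assert enteric_ch4(65774.25, 0.065) == pytest.approx(76.82, abs=0.01)


def test_enteric_ch4_rejects_unphysical_ym():
    with pytest.raises(ValueError):
        enteric_ch4(100.0, 0.5)


# ---------------------------------------------------------------- manure CH4
def test_manure_ch4_values():
    assert manure_ch4(0.0, 0.24, {"heap": 0.01}, {"heap": 1.0}) == 0.0
    got = manure_ch4(1000.0, 0.24, {"heap": 0.01}, {"heap": 1.0})
    assert got == pytest.approx(1.608, abs=1e-9)


def test_manure_ch4_monotone_in_heap_share():
    mcf = {"pasture": 0.01, "heap": 0.04}
    prev = -1.0
    for heap in (0.0, 0.3, 0.6, 1.0):
        got = manure_ch4(1000.0, 0.24, mcf, {"pasture": 1 - heap, "heap": heap})
        assert got > prev
        prev = got


def test_manure_ch4_rejects_bad_split():
    with pytest.raises(ValueError, match="sum to 1"):
        manure_ch4(10.0, 0.24, {"heap": 0.01}, {"heap": 0.5})


# ---------------------------------------------------------------- N flows
def test_n_flows_zero_diet(feeds):
    out = n_flows(Diet(intakes={}), feeds, milk_fpcm=0.0)
    assert out == {"n_intake": 0.0, "n_milk": 0.0, "n_excreted": 0.0}


def test_n_flows_linear_in_cp(feeds):
    lo = n_flows(uniform_diet(1000.0), feeds, 0.0)["n_intake"]
    feeds2 = dict(feeds)
    feeds2["pasture"] = herd.FeedItem("pasture", 0.55, 0.16)  # doubled CP
    hi = n_flows(uniform_diet(1000.0), feeds2, 0.0)["n_intake"]
    assert hi == pytest.approx(2 * lo)


def test_n_flows_independent_closed_form(feeds):
    # 3,565 kg DM at CP 0.10, milk N 0.53% of 1,729 kg FPCM
    feeds2 = {"pasture": herd.FeedItem("pasture", 0.55, 0.10)}
    out = n_flows(uniform_diet(3565.0), feeds2, 1729.0, milk_n_fraction=0.0053)
    expected_intake = 3565.0 * 0.10 / 6.25
    expected_excreted = expected_intake - 1729.0 * 0.0053
    assert out["n_intake"] == pytest.approx(expected_intake)
    assert out["n_excreted"] == pytest.approx(expected_excreted)


def test_n_flows_rejects_impossible_milk(feeds):
    with pytest.raises(ValueError, match="inconsistent"):
        n_flows(uniform_diet(10.0), feeds, milk_fpcm=10000.0)


# ---------------------------------------------------------------- N2O
def test_n2o_zero_inputs(factors):
    out = n2o_emissions(0.0, 0.0, factors)
    assert all(v == 0.0 for v in out.values())


def test_n2o_closed_form_direct():
    f = EmissionFactors(
        ef3_heap=Param(0.01), frac_gas=Param(0.0), frac_leach=Param(0.0),
        manure_split={"pasture": 0.0, "heap": 1.0},
    )
    out = n2o_emissions(100.0, 0.0, f)
    assert out["manure_direct"] == pytest.approx(100 * 0.01 * (44 / 28) * 298, rel=1e-9)
    assert out["soil_direct"] == 0.0


def test_n2o_routing_follows_split(factors):
    pasture_only = n2o_emissions(100.0, 0.0, factors, {"pasture": 1.0, "heap": 0.0})
    heap_only = n2o_emissions(100.0, 0.0, factors, {"pasture": 0.0, "heap": 1.0})
    assert pasture_only["manure_direct"] == 0.0 and pasture_only["soil_direct"] > 0
    assert heap_only["soil_direct"] == 0.0 and heap_only["manure_direct"] > 0


def test_fertilizer_n2o_linear_in_n(factors):
    one = n2o_emissions(0.0, 50.0, factors)["fertilizer"]
    two = n2o_emissions(0.0, 100.0, factors)["fertilizer"]
    assert two == pytest.approx(2 * one)


# ---------------------------------------------------------------- milk model
def test_maintenance_only_diet_gives_zero_milk(feeds):
    with pytest.warns(UserWarning, match="maintenance"):
        assert lifetime_milk(uniform_diet(500.0), feeds) == 0.0


def test_milk_monotone_in_digestibility(feeds):
    diet = uniform_diet(4000.0)
    prev = -1.0
    for dig in (0.50, 0.60, 0.70, 0.80):
        f = {"pasture": herd.FeedItem("pasture", dig, 0.12)}
        milk = lifetime_milk(diet, f)
        assert milk >= prev
        prev = milk


def test_calibration_fixture_returns_observed_yield(feeds):
    cal = herd.calibration_from_diet_table()
    diet = Diet(intakes={"pasture": 4391.0}, lps="MRA", scenario="FeCo")
    assert lifetime_milk(diet, feeds, calibration=cal) == 2489.0


def test_fpcm_identity_at_reference_composition():
    # 4% fat / 3.3% protein is within 0.1% of the raw mass by construction
    assert herd.fpcm(1000.0) == pytest.approx(999.0, abs=1.0)


# ---------------------------------------------------------------- intensity
def test_emission_intensity():
    assert emission_intensity(100.0, 50.0) == 2.0
    assert emission_intensity(200.0, 100.0) == 2.0  # scale invariance
    with pytest.raises(ValueError):
        emission_intensity(100.0, 0.0)


def test_intensity_consistent_with_fixture_back_computation():
    # FeCo yields 2,489 kg at intensity 2.38: back-computed emissions check
    assert emission_intensity(2.38 * 2489.0, 2489.0) == pytest.approx(2.38)


# ---------------------------------------------------------------- oracle equivalence
def test_tier2_kernels_match_single_expression_oracles():
    rng = np.random.default_rng(42)
    for _ in range(100):
        ge = rng.uniform(0, 1e5)
        ym = rng.uniform(0.01, 0.12)
        vs = rng.uniform(0, 2000)
        b0 = rng.uniform(0.1, 0.3)
        mcf = rng.uniform(0.005, 0.1)
        n = rng.uniform(0, 200)
        ef = rng.uniform(0.001, 0.05)
        assert enteric_ch4(ge, ym) == pytest.approx(ge * ym / 55.65, rel=1e-9)
        assert manure_ch4(vs, b0, {"s": mcf}, {"s": 1.0}) == pytest.approx(
            vs * b0 * 0.67 * mcf, rel=1e-9
        )
        f = EmissionFactors(
            ef3_heap=Param(ef), frac_gas=Param(0.0), frac_leach=Param(0.0),
            manure_split={"pasture": 0.0, "heap": 1.0},
        )
        assert n2o_emissions(n, 0.0, f)["manure_direct"] == pytest.approx(
            n * ef * (44 / 28) * 298, rel=1e-9
        )


# ---------------------------------------------------------------- breakdown properties
def test_breakdown_nonnegative_and_additive(feeds, factors):
    diet = Diet(intakes={"pasture": 2000.0, "napier": 1000.0, "concentrate": 450.0})
    br = cow_emissions(diet, feeds, factors, milk_fpcm=2000.0, n_fertilizer=20.0)
    d = br.as_dict()
    assert all(v >= 0 for v in d.values())
    assert br.total == pytest.approx(sum(d.values()))


def test_gwp_linearity_for_ch4_components(feeds):
    diet = Diet(intakes={"pasture": 3000.0, "concentrate": 450.0})
    f1 = EmissionFactors(gwp_ch4=25.0)
    f2 = EmissionFactors(gwp_ch4=50.0)
    b1, b2 = (cow_emissions(diet, feeds, f, 1500.0) for f in (f1, f2))
    assert b2.enteric_ch4 == pytest.approx(2 * b1.enteric_ch4)
    assert b2.manure_ch4 == pytest.approx(2 * b1.manure_ch4)
    for cat in ("soil_n2o_direct", "manure_n2o_direct", "concentrate_co2e"):
        assert getattr(b2, cat) == pytest.approx(getattr(b1, cat))


def test_better_forage_cuts_enteric_ch4_per_kg_milk(feeds, factors):
    """Replacing forage with higher-digestibility feed at equal gross energy
    lowers CH4 per kg milk (milk rises, enteric CH4 is unchanged)."""
    base = Diet(intakes={"pasture": 4000.0})
    improved = Diet(intakes={"napier": 4000.0})
    ge_b, ge_i = (gross_energy_intake(d, feeds) for d in (base, improved))
    assert ge_b == ge_i  # equal energy by construction
    milk_b, milk_i = (lifetime_milk(d, feeds) for d in (base, improved))
    ch4 = enteric_ch4(ge_b, factors.ym.mean)
    assert ch4 / milk_i < ch4 / milk_b


# ---------------------------------------------------------------- LHS uncertainty
def test_lhs_degenerate_ranges_give_zero_sd():
    out = lhs_uncertainty({"a": Param(1.0)}, lambda p: 10 * p["a"], n_samples=16, seed=0)
    assert out["value"]["sd"] == 0.0
    assert out["value"]["mean"] == 10.0


def test_lhs_uniform_linear_sd_limit():
    # a single U(a,b) parameter entering linearly: SD -> (b-a)/sqrt(12)
    out = lhs_uncertainty(
        {"a": Param(5.0, 2.0, 8.0)}, lambda p: p["a"], n_samples=4000, seed=1
    )
    assert out["value"]["sd"] == pytest.approx((8.0 - 2.0) / np.sqrt(12.0), rel=0.02)


def test_lhs_deterministic_given_seed():
    params = {"a": Param(1.0, 0.0, 2.0), "b": Param(3.0, 1.0, 5.0)}
    model = lambda p: p["a"] * p["b"]
    r1 = lhs_uncertainty(params, model, n_samples=64, seed=9)
    r2 = lhs_uncertainty(params, model, n_samples=64, seed=9)
    assert r1 == r2


def test_lhs_oat_quadrature_combination():
    params = {"a": Param(1.0, 0.0, 2.0), "b": Param(1.0, 0.0, 2.0)}
    out = lhs_uncertainty(params, lambda p: p["a"] + p["b"], mode="scenario_oat", seed=0)
    # each parameter contributes half-range 1.0; quadrature: sqrt(2)
    assert out["value"]["sd"] == pytest.approx(np.sqrt(2.0))


def test_param_validation():
    with pytest.raises(ValueError):
        Param(1.0, 2.0, 3.0)
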