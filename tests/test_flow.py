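"""Core mass-flow model: adoption transformation, ledger, shares."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishflow import (
    GLOBAL_HARVEST_T,
    AdoptionScenario,
    EffectiveRates,
    UtilisationParams,
    adoption_sweep,
    as_percent,
    effective_rates,
    flow_edges,
    mass_ledger,
    net_utilisation,
    share_breakdown,
)

fractions = st.floats(0.0, 1.0, allow_nan=False)


@st.composite
def utilisation_params(draw):
    d0 = draw(fractions)
    return UtilisationParams(
        region="test",
        a0=draw(fractions),
        b0=draw(fractions),
        c=draw(fractions),
        d0=d0,
        lim_a=draw(fractions),
        lim_b=draw(fractions),
        d_max=draw(st.floats(d0, 1.0, allow_nan=False)),
    )


def chain_oracle(a, b, c, d, m_h=1.0):
    """Independent step-by-step mass propagation through the chain."""
    food = a * m_h
    survives = b * food
    edible = c * survives
    byprod = survives - edible
    reused = d * byprod
    return edible + reused


@pytest.mark.parametrize(
    "x, expected",
    [
        (0.0, (0.89, 0.81, 0.30)),
        (1.0, (0.9648, 0.9164, 0.70)),
        (0.8, (0.94984, 0.89512, 0.62)),
    ],
)
def test_effective_rates_global(global_params, x, expected):
    r = effective_rates(global_params, x)
    assert (r.a, r.b, r.d) == pytest.approx(expected, abs=1e-12)
    assert r.c == global_params.c


@pytest.mark.parametrize(
    "rates, expected",
    [
        (EffectiveRates(0.89, 0.81, 0.65, 0.30), 0.5443),
        (EffectiveRates(1.0, 1.0, 0.4, 1.0), 1.0),
        (EffectiveRates(0.7, 0.6, 1.0, 0.3), 0.42),
    ],
)
def test_net_utilisation_examples(rates, expected):
    assert net_utilisation(rates) == pytest.approx(expected, abs=5e-5)


def test_baseline_and_adoption_percents(global_params):
    """The global chain delivers 54% today, 66% at x=0.5, 74% at x=0.8."""
    for x, pct in [(0.0, 54), (0.5, 66), (0.8, 74)]:
        f = net_utilisation(effective_rates(global_params, x))
        assert as_percent(f) == pct


def test_mass_ledger_global_baseline(global_params):
    led = mass_ledger(global_params, 0.0, GLOBAL_HARVEST_T)
    assert led.M2 == pytest.approx(20.35e6)  # 11% non-food
    assert led.M4 == pytest.approx(31.28e6, rel=1e-3)  # 31 Mt direct loss
    assert led.M_B - led.M_R == pytest.approx(32.67e6, rel=1e-3)
    assert led.f == pytest.approx(0.5443, abs=5e-5)


def test_mass_ledger_unit_mass(global_params):
    led = mass_ledger(global_params, 0.0, 1.0)
    assert led.M1 == pytest.approx(0.89)
    assert led.M3 == pytest.approx(0.89 * 0.81)
    assert led.M2 + led.M4 + led.M_D + led.M_B == pytest.approx(1.0, rel=1e-12)


def test_share_breakdown_baseline(global_params):
    sh = share_breakdown(mass_ledger(global_params, 0.0))
    assert sh.consumed == pytest.approx(0.544, abs=5e-4)
    assert sh.nonfood == pytest.approx(0.110, abs=5e-4)
    assert sh.byproduct_unused == pytest.approx(0.177, abs=5e-4)
    assert sh.loss == pytest.approx(0.169, abs=5e-4)


def test_share_breakdown_lossless():
    p = UtilisationParams("ideal", 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
    sh = share_breakdown(mass_ledger(p, 0.0, 10.0))
    assert (sh.consumed, sh.nonfood, sh.byproduct_unused, sh.loss) == (1, 0, 0, 0)


def test_adoption_sweep_examples(global_params):
    df = adoption_sweep(global_params, [0.0, 0.5, 0.8])
    assert df.f.tolist() == pytest.approx([0.544, 0.660, 0.737], abs=5e-4)
    assert df.f.is_monotonic_increasing
    single = adoption_sweep(global_params, [0.2])
    assert single.f.iloc[0] == pytest.approx(0.589, abs=5e-4)


def test_adoption_sweep_empty(global_params):
    df = adoption_sweep(global_params, [])
    assert df.empty and "f" in df.columns


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(a0=1.2), "a0"),
        (dict(b0=-0.1), "b0"),
        (dict(d0=0.8, d_max=0.5), "d_max"),
        (dict(lim_b=float("nan")), "lim_b"),
    ],
)
def test_params_validation_names_field(kwargs, field):
    base = dict(region="bad", a0=0.89, b0=0.81, c=0.65, d0=0.30,
                lim_a=0.68, lim_b=0.56, d_max=0.70)
    with pytest.raises(ValueError, match=field):
        UtilisationParams(**{**base, **kwargs})


def test_scenario_and_mass_validation(global_params):
    with pytest.raises(ValueError, match="x"):
        AdoptionScenario(1.5)
    with pytest.raises(ValueError, match="M_H"):
        mass_ledger(global_params, 0.0, 0.0)
    with pytest.raises(ValueError, match="M_H"):
        mass_ledger(global_params, 0.0, -5.0)


@given(params=utilisation_params(), x=fractions,
       m_h=st.floats(1e-3, 1e9, allow_nan=False))
def test_conservation_and_equivalence(params, x, m_h):
    """Full partition holds to 1e-12 and the closed form matches the
    independently-propagated chain oracle."""
    led = mass_ledger(params, x, m_h)
    assert led.M2 + led.M4 + led.M_D + led.M_B == pytest.approx(m_h, rel=1e-12)
    r = effective_rates(params, x)
    oracle = chain_oracle(r.a, r.b, r.c, r.d, m_h) / m_h
    assert net_utilisation(r) == pytest.approx(oracle, rel=1e-12, abs=1e-15)
    assert led.f == pytest.approx(oracle, rel=1e-12, abs=1e-15)


@given(params=utilisation_params(), x1=fractions, x2=fractions)
def test_monotonicity_in_adoption(params, x1, x2):
    x1, x2 = min(x1, x2), max(x1, x2)
    r1, r2 = effective_rates(params, x1), effective_rates(params, x2)
    assert r2.a >= r1.a - 1e-15
    assert r2.b >= r1.b - 1e-15
    assert r2.d >= r1.d - 1e-15
    assert net_utilisation(r2) >= net_utilisation(r1) - 1e-12


@given(params=utilisation_params())
def test_endpoint_limits(params):
    r = effective_rates(params, 1.0)
    assert r.a == pytest.approx(params.a0 + (1 - params.a0) * params.lim_a, abs=1e-15)
    assert r.b == pytest.approx(1 - (1 - params.b0) * (1 - params.lim_b), abs=1e-15)
    assert r.d == pytest.approx(params.d_max, abs=1e-15)
    r0 = effective_rates(params, 0.0)
    assert r0.a == params.a0 and r0.d == params.d0
    assert r0.b == pytest.approx(params.b0, abs=1e-15)


@given(params=utilisation_params(), x=fractions)
def test_f_bounded_and_rates_improve(params, x):
    r = effective_rates(params, x)
    assert 0.0 <= net_utilisation(r) <= 1.0
    assert r.a >= params.a0 - 1e-12
    assert r.b >= params.b0 - 1e-12
    assert r.d >= params.d0 - 1e-12


def test_flow_edges_structure(global_params):
    led = mass_ledger(global_params, 0.0)
    df = flow_edges(led, "Global", 0.0)
    assert list(df.source_node[:2]) == ["harvest", "harvest"]
    assert df.mass_t[df.source_node == "harvest"].sum() == pytest.approx(led.M_H)
    assert df.loc[df.target_node == "unutilised_byproduct", "mass_t"].iloc[0] == (
        pytest.approx(led.M_B - led.M_R)
    )
    assert df.share.iloc[:2].sum() == pytest.approx(1.0)


def test_as_percent_half_even():
    assert as_percent(0.625) == 62  # 62.5 rounds to even
    assert as_percent(0.875) == 88
    assert as_percent(0.5442795) == 54
    assert as_percent(0.737142, 1) == 73.7
    assert isinstance(as_percent(0.5), int)
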