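import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from craydeb import (
    Environment,
    OrganismState,
    arrhenius_1p,
    arrhenius_5p,
    functional_response,
    half_saturation,
    initial_reserve,
    integrate_lifecycle,
    load_species,
    metabolic_fluxes,
    physical_length,
    state_derivative,
    wet_weight,
)

from conftest import SPECIES


# ---------------------------------------------------------------------------
# temperature correction
# ---------------------------------------------------------------------------

def test_arrhenius_1p_reference_and_values():
    assert arrhenius_1p(293.15, 8000.0) == pytest.approx(1.0)
    # direct evaluation of exp(TA/Tref - TA/T)
    assert arrhenius_1p(285.15, 8000.0) == pytest.approx(0.4650, abs=5e-5)
    assert arrhenius_1p(297.15, 8000.0) == pytest.approx(1.4439, abs=5e-5)


def test_arrhenius_1p_monotone_in_temperature():
    temps = np.linspace(275.15, 305.15, 40)
    vals = [arrhenius_1p(T, 8000.0) for T in temps]
    assert np.all(np.diff(vals) > 0)


def test_arrhenius_5p_equals_one_at_reference(all_female):
    for p in all_female.values():
        assert arrhenius_5p(p.Tref, p, "combined") == pytest.approx(1.0)
        assert arrhenius_5p(p.Tref, p, "piecewise") == pytest.approx(1.0)


def test_arrhenius_5p_marbled_crayfish_at_12p5C(pv):
    # hand evaluation of both conventions at 285.65 K
    assert arrhenius_5p(285.65, pv, "combined") == pytest.approx(0.251, abs=1e-3)
    assert arrhenius_5p(285.65, pv, "piecewise") == pytest.approx(0.241, abs=1e-3)


def test_arrhenius_5p_piecewise_below_one_parameter(all_female):
    # boundary terms can only depress rates relative to the in-niche form
    for p in all_female.values():
        for T in (278.15, 284.15, 290.15):
            assert arrhenius_5p(T, p, "piecewise") <= arrhenius_1p(T, p.TA) + 1e-12


def test_arrhenius_5p_continuous_near_reference(pv):
    for form in ("combined", "piecewise"):
        lo = arrhenius_5p(pv.Tref - 1e-7, pv, form)
        hi = arrhenius_5p(pv.Tref + 1e-7, pv, form)
        assert lo == pytest.approx(hi, rel=1e-5)


def test_arrhenius_5p_unknown_form_raises(pv):
    with pytest.raises(ValueError):
        arrhenius_5p(290.0, pv, form="banana")


# ---------------------------------------------------------------------------
# food
# ---------------------------------------------------------------------------

def test_half_saturation_proportional_to_assimilation(aa):
    k1 = half_saturation(aa)
    k2 = half_saturation(aa.replace(pAm=2 * aa.pAm))
    assert k2 == pytest.approx(2 * k1)


def test_half_saturation_species_ratio(aa, pl):
    # only the assimilation-rate ratio matters at shared kapX, Fm
    assert half_saturation(pl) / half_saturation(aa) == pytest.approx(
        253.508 / 192.025
    )


def test_functional_response_shape(aa):
    KX = half_saturation(aa)
    assert functional_response(0.0, KX) == 0.0
    assert functional_response(KX, KX) == pytest.approx(0.5)
    assert functional_response(4 * KX, KX) == pytest.approx(0.8)
    with pytest.raises(ValueError):
        functional_response(-1.0, KX)


# ---------------------------------------------------------------------------
# fluxes
# ---------------------------------------------------------------------------

@st.composite
def random_states(draw):
    sid = draw(st.sampled_from(SPECIES))
    p = load_species(sid)
    V = draw(st.floats(1e-6, 40.0))
    e = draw(st.floats(0.05, 1.2))  # scaled reserve density
    EH = draw(st.floats(0.0, 1.5 * p.EHp))
    f = draw(st.floats(0.0, 1.1))
    cT = draw(st.floats(0.1, 2.0))
    return p, OrganismState(E=e * p.Em * V, V=V, EH=EH), f, cT


@given(random_states())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_kappa_rule_balance_to_machine_precision(case):
    """kappa*pC = pS + pG and (1-kappa)*pC = pJ + pR, exactly."""
    p, state, f, cT = case
    fx = metabolic_fluxes(state, p, f, cT)
    scale = max(abs(fx.pC), 1.0)
    assert abs(p.kappa * fx.pC - fx.pS - fx.pG) <= 1e-12 * scale
    assert abs((1 - p.kappa) * fx.pC - fx.pJ - fx.pR) <= 1e-12 * scale


@given(random_states())
@settings(max_examples=50, deadline=None, derandomize=True)
def test_embryos_do_not_assimilate(case):
    p, state, f, cT = case
    embryo = OrganismState(E=state.E, V=state.V, EH=0.5 * p.EHb)
    assert metabolic_fluxes(embryo, p, f, cT).pA == 0.0


def test_equilibrium_assimilation_equals_mobilization(aa):
    # at the ultimate state with f = 1 the reserve is in steady state
    L = aa.Lm
    state = OrganismState(E=aa.Em * L**3, V=L**3, EH=aa.EHp)
    fx = metabolic_fluxes(state, aa, f=1.0)
    assert fx.pA == pytest.approx(aa.pAm * L * L)
    assert fx.pC == pytest.approx(fx.pA, rel=1e-12)
    assert fx.pG == pytest.approx(0.0, abs=1e-9 * fx.pC)


def test_state_derivative_routing(aa):
    L = 0.5 * aa.Lm
    juv = OrganismState(E=aa.Em * L**3, V=L**3, EH=0.5 * aa.EHp)
    d = state_derivative(juv, aa, f=1.0)
    assert d.ER == 0.0 and d.EH > 0.0
    adult = OrganismState(E=aa.Em * L**3, V=L**3, EH=aa.EHp)
    d = state_derivative(adult, aa, f=1.0)
    assert d.EH == 0.0 and d.ER > 0.0


def test_growth_stops_at_asymptote(aa):
    f = 0.7
    L = f * aa.Lm
    st_eq = OrganismState(E=f * aa.Em * L**3, V=L**3, EH=aa.EHp)
    d = state_derivative(st_eq, aa, f=f)
    assert d.V == pytest.approx(0.0, abs=1e-10)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def test_physical_length_identity_and_ratio(aa):
    assert physical_length(8.0, 1.0) == pytest.approx(2.0)
    TL = physical_length(8.0, aa.deltaM)
    CL = physical_length(8.0, aa.deltaMC)
    assert CL / TL == pytest.approx(aa.deltaM / aa.deltaMC)
    with pytest.raises(ValueError):
        physical_length(1.0, 0.0)


def test_wet_weight_structure_only_and_monotone(aa):
    s0 = OrganismState(E=0.0, V=3.0, EH=aa.EHp, ER=0.0)
    assert wet_weight(s0, aa) == pytest.approx(aa.dV * 3.0)
    s1 = OrganismState(E=0.0, V=3.0, EH=aa.EHp, ER=500.0)
    assert wet_weight(s1, aa) > wet_weight(s0, aa)


# ---------------------------------------------------------------------------
# life-cycle integration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sid", SPECIES)
def test_stage_events_are_ordered(sid, all_female):
    p = all_female[sid]
    E0 = initial_reserve(p)
    env = Environment.constant(temp_K=p.Tref, f=1.0)
    traj = integrate_lifecycle(p, env, E0, horizon=6000.0)
    ev = traj.events
    assert set(ev) >= {"hatch", "birth", "puberty"}
    assert ev["hatch"].age < ev["birth"].age < ev["puberty"].age


def test_trajectory_invariants(pv):
    E0 = initial_reserve(pv)
    env = Environment.constant(temp_K=pv.Tref, f=1.0)
    traj = integrate_lifecycle(pv, env, E0, horizon=4000.0)
    EH = traj.array("EH")
    S = traj.array("S")
    ER = traj.array("ER")
    assert np.all(np.diff(EH) >= -1e-9 * pv.EHp)
    assert np.all(ER >= 0.0)
    assert np.all((S >= 0.0) & (S <= 1.0)) and np.all(np.diff(S) <= 1e-12)
    # no reproduction buffer before puberty
    juvenile = EH < pv.EHp * (1 - 1e-9)
    assert np.all(ER[juvenile] == 0.0)
    df = traj.to_frame()
    assert {"age_d", "TL_cm", "Ww_g", "pA_Jd"} <= set(df.columns)
    # observables consistent with state at every node
    assert df["L_cm"].to_numpy() == pytest.approx(df["V_cm3"].to_numpy() ** (1 / 3))


def test_asymptotic_length_matches_closed_form(aa):
    f = 0.8
    E0 = initial_reserve(aa, f)
    env = Environment.constant(temp_K=aa.Tref, f=f)
    traj = integrate_lifecycle(aa, env, E0, horizon=25_000.0)
    assert traj.L[-1] == pytest.approx(f * aa.Lm, rel=1e-3)


def test_growth_is_von_bertalanffy(pl):
    """Post-birth structural length approaches the asymptote exponentially:
    log(L_inf - L) is linear in time (checked by residuals of a line fit)."""
    E0 = initial_reserve(pl)
    env = Environment.constant(temp_K=pl.Tref, f=1.0)
    traj = integrate_lifecycle(pl, env, E0, horizon=3000.0, n_points=400)
    t, L = traj.age, traj.L
    after_birth = t > traj.events["birth"].age + 10
    gap = pl.Lm - L[after_birth]
    y = np.log(gap)
    x = t[after_birth]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    assert np.max(np.abs(resid)) < 5e-3
    # von Bertalanffy rate constant: pM/3 / (EG + kappa*Em)
    rB = pl.pM / 3.0 / (pl.EG + pl.kappa * pl.Em)
    assert -slope == pytest.approx(rB, rel=1e-2)


def test_temperature_rescales_time_exactly(pv):
    """With constant f, trajectories at two temperatures are the same curve
    with time scaled by the ratio of the correction factors."""
    E0 = initial_reserve(pv)
    T2 = 288.15
    c2 = arrhenius_1p(T2, pv.TA, pv.Tref)
    tr1 = integrate_lifecycle(pv, Environment.constant(pv.Tref, f=1.0), E0,
                              horizon=800.0)
    tr2 = integrate_lifecycle(pv, Environment.constant(T2, f=1.0), E0,
                              horizon=800.0 / c2)
    for name in ("hatch", "birth", "puberty"):
        assert tr2.events[name].age * c2 == pytest.approx(
            tr1.events[name].age, rel=1e-6
        )
        assert tr2.events[name].state.V == pytest.approx(
            tr1.events[name].state.V, rel=1e-6
        )


def test_food_density_forcing_equivalent_to_f(pl):
    KX = half_saturation(pl)
    E0 = initial_reserve(pl, 0.8)
    tr_f = integrate_lifecycle(pl, Environment.constant(pl.Tref, f=0.8), E0,
                               horizon=2000.0)
    tr_x = integrate_lifecycle(pl, Environment.constant(pl.Tref, X=4.0 * KX),
                               E0, horizon=2000.0)
    assert tr_x.events["puberty"].age == pytest.approx(
        tr_f.events["puberty"].age, rel=1e-8
    )


def test_environment_requires_exactly_one_food_spec():
    with pytest.raises(ValueError):
        Environment(temperature=293.15)
    with pytest.raises(ValueError):
        Environment(temperature=293.15, f=1.0, X=10.0)


def test_integration_failure_reports_context(pv):
    with pytest.raises(ValueError):
        integrate_lifecycle(pv, Environment.constant(pv.Tref, f=1.0),
                            E0=-1.0, horizon=100.0)
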