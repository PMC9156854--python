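import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from craydeb import (
    OrganismState,
    arrhenius_1p,
    initial_reserve,
    life_history_traits,
    max_reproduction_rate,
    mean_lifespan,
    metabolic_fluxes,
    min_f_for_puberty,
    min_f_for_puberty_asymptotic,
    stage_events,
    ultimate_total_length,
)
from craydeb.life_history import reference_trajectory, ultimate_structural_length

from conftest import SPECIES


# ---------------------------------------------------------------------------
# initial reserve (egg energy)
# ---------------------------------------------------------------------------

def _bisection_oracle_E0(p, f=1.0, tol=1e-8):
    """Brute-force oracle: RK45 embryo integration + manual bisection on the
    reserve density at the birth threshold (independent of the shooting
    solver's LSODA/brentq path)."""

    def density_gap(E0):
        def rhs(t, y):
            E, V, EH = y
            L = max(V, 0.0) ** (1 / 3)
            pC = E * (p.v * p.EG * L**2 + p.pM * V) / (p.EG * V + p.kappa * E)
            return [-pC, (p.kappa * pC - p.pM * V) / p.EG,
                    (1 - p.kappa) * pC - p.kJ * EH]

        def at_birth(t, y):
            return y[2] - p.EHb
        at_birth.terminal = True
        at_birth.direction = 1
        sol = solve_ivp(rhs, (0, 2000), [E0, 1e-9, 0.0], method="RK45",
                        rtol=1e-10, atol=1e-12, events=at_birth)
        if not sol.t_events[0].size or sol.y_events[0][0][0] <= 0:
            return -1.0
        E_b, V_b, _ = sol.y_events[0][0]
        return E_b / V_b - f * p.pAm / p.v

    lo, hi = 1.0, 200.0
    while hi - lo > tol * hi:
        mid = 0.5 * (lo + hi)
        if density_gap(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def test_initial_reserve_matches_bisection_oracle(pv):
    E0 = initial_reserve(pv)
    assert E0 == pytest.approx(_bisection_oracle_E0(pv), rel=1e-6)


def test_initial_reserve_strictly_increasing_in_f(pl):
    values = [initial_reserve(pl, f) for f in (0.6, 0.8, 1.0)]
    assert values[0] < values[1] < values[2]


def test_initial_reserve_rejects_bad_f(pl):
    with pytest.raises(ValueError):
        initial_reserve(pl, 0.0)
    with pytest.raises(ValueError):
        initial_reserve(pl, 1.5)


def test_reserve_density_at_birth_equals_maternal_level(pl):
    f = 0.85
    traj = reference_trajectory(pl, f, terminate_at="puberty", n_points=3)
    birth = traj.events["birth"].state
    assert birth.E / birth.V == pytest.approx(f * pl.Em, rel=1e-5)


# ---------------------------------------------------------------------------
# stage events
# ---------------------------------------------------------------------------

def test_marbled_crayfish_early_ages(pv):
    # at its typical temperature (= Tref) these reproduce the reference
    # predictions: hatch at 24.71 d and birth at 33.46 d from egg laying
    ev = stage_events(pv)
    assert ev.age_h == pytest.approx(24.71, rel=0.01)
    assert ev.age_b == pytest.approx(33.46, rel=0.01)
    assert ev.L_h == pytest.approx(0.3448, rel=0.01)


def test_stage_lengths_temperature_invariant_and_ages_rescale(pl):
    ev_cold = stage_events(pl, T=283.15)
    ev_warm = stage_events(pl, T=291.15)
    assert ev_cold.L_p == pytest.approx(ev_warm.L_p, rel=1e-9)
    ratio = arrhenius_1p(291.15, pl.TA) / arrhenius_1p(283.15, pl.TA)
    assert ev_cold.age_p / ev_warm.age_p == pytest.approx(ratio, rel=1e-9)


def test_puberty_not_reached_below_threshold_food(aa):
    f_low = 0.9 * min_f_for_puberty_asymptotic(aa)
    ev = stage_events(aa, f=f_low, horizon=20_000.0)
    assert not ev.puberty_reached
    assert math.isnan(ev.age_p)


# ---------------------------------------------------------------------------
# ultimate size
# ---------------------------------------------------------------------------

def test_ultimate_length_linear_in_f(at):
    assert ultimate_total_length(at, 0.5) == pytest.approx(
        0.5 * ultimate_total_length(at, 1.0)
    )


def test_ultimate_length_male_variant(aa):
    from craydeb import load_species

    male = load_species("astacus_astacus", "male")
    assert ultimate_total_length(male) > ultimate_total_length(aa)


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sid", SPECIES)
def test_rmax_two_path_consistency(sid, all_female):
    """The analytic R_max equals kapR*pR/E0 with pR evaluated by the flux
    machinery at the ultimate state."""
    p = all_female[sid]
    f = 0.9
    E0 = initial_reserve(p, f)
    L = ultimate_structural_length(p, f)
    state = OrganismState(E=f * p.Em * L**3, V=L**3, EH=p.EHp)
    pR = metabolic_fluxes(state, p, f).pR
    direct = p.kapR * pR / E0
    assert max_reproduction_rate(p, f, T=p.Tref, E0=E0) == pytest.approx(
        direct, rel=1e-9
    )


def test_rmax_clamped_at_zero(at):
    starved = at.replace(kJ=5.0)  # maturity maintenance swamps the budget
    assert max_reproduction_rate(starved, T=at.Tref, E0=70.0) == 0.0


def test_rmax_temperature_correction(pl):
    r_ref = max_reproduction_rate(pl, T=pl.Tref)
    r_typ = max_reproduction_rate(pl, T=pl.Ttyp)
    assert r_typ / r_ref == pytest.approx(
        arrhenius_1p(pl.Ttyp, pl.TA), rel=1e-9
    )


# ---------------------------------------------------------------------------
# puberty-enabling food level
# ---------------------------------------------------------------------------

def test_min_f_matches_grid_scan_oracle(pv):
    """Coarse brute-force scan over f with long-horizon integration brackets
    the bisection result."""
    fp = min_f_for_puberty(pv)
    grid = np.arange(0.20, 0.30, 0.01)
    reached = []
    for f in grid:
        traj = reference_trajectory(pv, f, horizon=30_000.0, n_points=3,
                                    include_ageing=False,
                                    terminate_at="puberty")
        reached.append("puberty" in traj.events)
    first = grid[int(np.argmax(reached))]
    assert first - 0.01 <= fp <= first


def test_min_f_close_to_asymptotic_bound(aa):
    # the bisection (tolerance 1e-4) sits essentially on the closed-form
    # asymptotic bound when given a long horizon
    fp = min_f_for_puberty(aa)
    fa = min_f_for_puberty_asymptotic(aa)
    assert fp == pytest.approx(fa, abs=2e-4)


def test_min_f_species_contrast(all_female):
    """The marbled crayfish matures at far lower food levels than the three
    Astacidae -- the key competitive asymmetry."""
    fp = {sid: min_f_for_puberty_asymptotic(p) for sid, p in all_female.items()}
    assert fp["procambarus_virginalis"] < 0.3
    assert fp["astacus_astacus"] > 0.4
    assert fp["pacifastacus_leniusculus"] > 0.4
    assert fp["austropotamobius_torrentium"] > 0.39
    assert all(v < 1.0 for v in fp.values())


# ---------------------------------------------------------------------------
# lifespan
# ---------------------------------------------------------------------------

def test_no_ageing_no_death(pv):
    immortal = pv.replace(ha=0.0)
    traj = reference_trajectory(immortal, horizon=2000.0, include_ageing=True)
    assert np.all(traj.array("S") == 1.0)


def test_lifespan_shrinks_with_warming(pv):
    cool = mean_lifespan(pv, T=290.15)
    warm = mean_lifespan(pv, T=296.15)
    assert warm < cool


def test_lifespan_magnitudes(at, pv):
    # regression values for the survival-curve mean at Ttyp (sG = 0); the
    # long-lived stone crayfish and short-lived marbled crayfish should
    # stay an order of magnitude apart
    assert mean_lifespan(at) == pytest.approx(9473, rel=0.02)
    assert mean_lifespan(pv) == pytest.approx(1568, rel=0.02)


# ---------------------------------------------------------------------------
# bundled record
# ---------------------------------------------------------------------------

def test_trait_record_is_consistent(pv):
    rec = life_history_traits(pv, compute_fp_min=False, compute_lifespan=False)
    assert rec.puberty_reached
    assert rec.L_h < rec.L_p < rec.TL_inf
    assert rec.E0 == pytest.approx(initial_reserve(pv), rel=1e-9)
    assert rec.Rmax > 0
    d = rec.to_dict()
    assert d["species"] == "procambarus_virginalis"
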