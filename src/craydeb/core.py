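"""Standard DEB dynamics: fluxes, temperature correction, life-cycle integration.

The model tracks an individual through reserve energy E (J), structural
volume V (cm^3), cumulative maturity E_H (J) and, after puberty, a
reproduction buffer E_R (J).  Energy assimilated from food enters the
reserve; a fixed fraction ``kappa`` of the mobilized flux pays somatic
maintenance and growth, the rest pays maturity maintenance and maturation
(or reproduction, once E_H has reached the puberty threshold).  Stage
transitions (hatching, birth = onset of feeding, puberty) occur when E_H
crosses the corresponding threshold.

All rate parameters are multiplied by an Arrhenius temperature correction
before flux evaluation: a 1-parameter form inside the thermal optimum and a
5-parameter form (two variants, see :func:`arrhenius_5p`) covering the
boundaries of the tolerance range.  Food enters through the scaled
functional response f = X/(X + K_X) in [0, 1], with f > 1 permitted to
represent food of above-reference quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .species import SpeciesParameters

__all__ = [
    "OrganismState",
    "FluxSet",
    "Environment",
    "Trajectory",
    "StageEvent",
    "arrhenius_1p",
    "arrhenius_5p",
    "temperature_correction",
    "half_saturation",
    "functional_response",
    "metabolic_fluxes",
    "state_derivative",
    "integrate_lifecycle",
    "physical_length",
    "wet_weight",
    "celsius_to_kelvin",
]

#: Initial structural volume of the embryo, cm^3 (avoids the singular V = 0
#: start; results are insensitive to the exact value well below 1e-6).
V_EPSILON = 1e-9


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + 273.15


# ---------------------------------------------------------------------------
# temperature correction
# ---------------------------------------------------------------------------

def arrhenius_1p(T: float, TA: float, Tref: float = 293.15) -> float:
    """1-parameter Arrhenius correction exp(TA/Tref - TA/T).

    Strictly increasing in T and equal to 1 at the reference temperature.
    Appropriate within the species' optimal thermal niche.
    """
    return math.exp(TA / Tref - TA / T)


def arrhenius_5p(T: float, params: SpeciesParameters,
                 form: str = "combined") -> float:
    """5-parameter Arrhenius correction covering the full tolerance range.

    Adds low/high boundary temperatures (``TLcrit``, ``TH``) and boundary
    Arrhenius temperatures (``TAL``, ``TAH``) so that rates fall off outside
    the thermal optimum.  Two algebraic conventions are supported; both
    equal 1 at ``Tref`` and never exceed the 1-parameter factor.

    ``form="combined"`` (default): single ratio with both boundary terms,

        c_T = c_T^(1) * (1 + e_L(Tref) + e_H(Tref)) / (1 + e_L(T) + e_H(T)),

    with e_L(T) = exp(TAL/T - TAL/TLcrit), e_H(T) = exp(TAH/TH - TAH/T).

    ``form="piecewise"``: the low-boundary ratio applies for T <= Tref and
    the high-boundary ratio for T > Tref.
    """
    TA, TAL, TAH = params.TA, params.TAL, params.TAH
    TL, TH, Tref = params.TLcrit, params.TH, params.Tref
    c1 = arrhenius_1p(T, TA, Tref)

    def e_low(temp: float) -> float:
        return math.exp(TAL / temp - TAL / TL)

    def e_high(temp: float) -> float:
        return math.exp(TAH / TH - TAH / temp)

    if form == "combined":
        num = 1.0 + e_low(Tref) + e_high(Tref)
        den = 1.0 + e_low(T) + e_high(T)
        return c1 * num / den
    if form == "piecewise":
        if T <= Tref:
            return c1 * (1.0 + e_low(Tref)) / (1.0 + e_low(T))
        return c1 * (1.0 + e_high(Tref)) / (1.0 + e_high(T))
    raise ValueError(f"unknown 5-parameter form {form!r}")


def temperature_correction(T: float, params: SpeciesParameters,
                           mode: str = "one_parameter",
                           form: str = "combined") -> float:
    """Dispatch to the configured Arrhenius correction."""
    if mode == "one_parameter":
        return arrhenius_1p(T, params.TA, params.Tref)
    if mode == "five_parameter":
        return arrhenius_5p(T, params, form=form)
    raise ValueError(f"unknown correction mode {mode!r}")


# ---------------------------------------------------------------------------
# food
# ---------------------------------------------------------------------------

def half_saturation(params: SpeciesParameters) -> float:
    """Half-saturation food density K_X = {p_Am}/(kappa_X * {F_m}).

    Proportional to the assimilation rate at fixed digestion efficiency and
    searching rate, which is what makes a shared food density translate into
    species-specific functional responses.
    """
    return params.pAm / (params.kapX * params.Fm)


def functional_response(X: float, K_X: float) -> float:
    """Scaled functional response f = X/(X + K_X) in [0, 1)."""
    if np.any(np.asarray(X) < 0):
        raise ValueError("food density X must be non-negative")
    if K_X <= 0:
        raise ValueError("half-saturation constant K_X must be positive")
    return X / (X + K_X)


@dataclass
class Environment:
    """Forcing for a life-cycle integration.

    ``temperature`` is either a constant (K) or a callable of age (d).
    Exactly one of ``f`` (scaled functional response, possibly > 1) and
    ``X`` (food density, converted via the species K_X) must be given;
    either may be a callable of age.
    """

    temperature: float | object = 293.15
    f: float | object | None = None
    X: float | object | None = None
    correction: str = "one_parameter"     # or "five_parameter"
    ct5_form: str = "combined"            # or "piecewise"

    def __post_init__(self) -> None:
        if (self.f is None) == (self.X is None):
            raise ValueError("specify exactly one of f and X")

    @classmethod
    def constant(cls, temp_K: float = 293.15, f: float | None = None,
                 X: float | None = None, **kw) -> "Environment":
        return cls(temperature=temp_K, f=f, X=X, **kw)

    def temp_at(self, t: float) -> float:
        T = self.temperature(t) if callable(self.temperature) else self.temperature
        if T <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        return T

    def f_at(self, t: float, params: SpeciesParameters) -> float:
        if self.f is not None:
            return self.f(t) if callable(self.f) else self.f
        X = self.X(t) if callable(self.X) else self.X
        return functional_response(X, half_saturation(params))

    def ct_at(self, t: float, params: SpeciesParameters) -> float:
        return temperature_correction(
            self.temp_at(t), params, self.correction, self.ct5_form
        )


# ---------------------------------------------------------------------------
# state, fluxes, derivatives
# ---------------------------------------------------------------------------

@dataclass
class OrganismState:
    """Instantaneous state of an individual.

    ``q`` (1/d^2) and ``h`` (1/d) are the ageing acceleration and hazard of
    the standard DEB ageing process; ``S`` is the survival probability.
    """

    E: float
    V: float
    EH: float
    ER: float = 0.0
    q: float = 0.0
    h: float = 0.0
    S: float = 1.0

    @property
    def L(self) -> float:
        """Structural length V^(1/3), cm."""
        return max(self.V, 0.0) ** (1.0 / 3.0)


@dataclass
class FluxSet:
    """Energy fluxes, J/d (assimilation, mobilization, somatic maintenance,
    maturity maintenance, growth, maturation/reproduction)."""

    pA: float
    pC: float
    pS: float
    pJ: float
    pG: float
    pR: float


def metabolic_fluxes(state: OrganismState, params: SpeciesParameters,
                     f: float, cT: float = 1.0,
                     feeding: bool | None = None) -> FluxSet:
    """Evaluate the standard DEB fluxes at one state.

    All rate parameters ({p_Am}, v, [p_M], k_J) are multiplied by the
    temperature correction ``cT`` before evaluation.  Embryos (E_H below the
    birth threshold) do not assimilate; ``feeding`` overrides that check
    (used by the segmented integrator, whose stage is fixed per segment).
    The kappa-rule balances hold exactly by construction:
    kappa*pC = pS + pG and (1-kappa)*pC = pJ + pR.
    """
    if cT <= 0:
        raise ValueError("temperature correction factor must be positive")
    pAm = params.pAm * cT
    v = params.v * cT
    pM = params.pM * cT
    kJ = params.kJ * cT

    V = max(state.V, 0.0)
    E = max(state.E, 0.0)
    L = V ** (1.0 / 3.0)
    L2 = L * L

    pS = pM * V
    den = params.EG * V + params.kappa * E
    pC = E * (v * params.EG * L2 + pS) / den if den > 0 else 0.0
    if feeding is None:
        feeding = state.EH >= params.EHb
    pA = pAm * f * L2 if feeding else 0.0
    pG = params.kappa * pC - pS
    pJ = kJ * state.EH
    pR = (1.0 - params.kappa) * pC - pJ
    return FluxSet(pA=pA, pC=pC, pS=pS, pJ=pJ, pG=pG, pR=pR)


def state_derivative(state: OrganismState, params: SpeciesParameters,
                     f: float, cT: float = 1.0,
                     stage: int | None = None) -> OrganismState:
    """Time derivative of the state (returned in state layout, units 1/d).

    dE/dt = pA - pC; dV/dt = pG/[E_G]; the (1-kappa) branch feeds maturity
    below puberty and the reproduction buffer at/after puberty.  The ageing
    accumulators follow the standard DEB ageing ODE pair driven by the
    Weibull ageing acceleration ``ha`` (temperature-corrected by cT^2 so
    that trajectories rescale exactly in time) and the Gompertz coefficient
    ``sG``; ageing starts at birth (embryonic damage is neglected).

    ``stage`` (0 = embryo, 1 = juvenile, 2 = adult) pins the life-stage
    branches regardless of the instantaneous maturity; the segmented
    integrator uses this so each segment stays free of switching
    discontinuities.  Left as None, the branches follow the thresholds.
    """
    if stage is None:
        feeding = state.EH >= params.EHb
        adult = state.EH >= params.EHp
    else:
        feeding = stage >= 1
        adult = stage == 2
    fx = metabolic_fluxes(state, params, f, cT, feeding=feeding)
    dE = fx.pA - fx.pC
    dV = fx.pG / params.EG
    dEH = 0.0 if adult else fx.pR
    dER = fx.pR if adult else 0.0

    dq = dh = 0.0
    if feeding and state.V > 0:
        V = state.V
        Vm = params.Lm ** 3
        e_scaled = state.E / (V * params.Em)
        r = fx.pG / (params.EG * V)  # specific growth rate, 1/d
        L = V ** (1.0 / 3.0)
        dq = ((state.q * (V / Vm) * params.sG + params.ha * cT * cT)
              * e_scaled * (params.v * cT / L - r) - r * state.q)
        dh = state.q - r * state.h
    dS = -state.h * max(state.S, 0.0)
    return OrganismState(E=dE, V=dV, EH=dEH, ER=dER, q=dq, h=dh, S=dS)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def physical_length(V: float, shape: float) -> float:
    """Physical length V^(1/3)/shape, cm (shape = delta_M or delta_MC)."""
    if shape <= 0:
        raise ValueError("shape coefficient must be positive")
    return np.maximum(np.asarray(V), 0.0) ** (1.0 / 3.0) / shape


def wet_weight(state: OrganismState, params: SpeciesParameters) -> float:
    """Wet weight dV*V + (wE/muE)*(E + ER), g.

    Composition-dependent: the shipped defaults reproduce the reference
    ultimate-weight convention but were not part of the primary parameter
    estimation, so weight outputs should be treated as indicative.
    """
    return params.dV * state.V + (params.wE / params.muE) * (state.E + state.ER)


# ---------------------------------------------------------------------------
# life-cycle integration
# ---------------------------------------------------------------------------

@dataclass
class StageEvent:
    name: str        # "hatch" | "birth" | "puberty"
    age: float       # d, from egg laying (includes the t0 offset)
    state: OrganismState


@dataclass
class Trajectory:
    """Result of a life-cycle integration.

    ``age`` runs from egg laying and includes the development-delay offset
    t0 (temperature-corrected when ``correct_t0`` is on); the ODE states are
    held at their initial values during the delay.
    """

    params: SpeciesParameters
    age: np.ndarray                       # d
    states: list[OrganismState]
    fluxes: list[FluxSet]
    events: dict[str, StageEvent]
    t0_offset: float
    success: bool = True
    message: str = ""

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(s, attr) for s in self.states])

    @property
    def L(self) -> np.ndarray:
        return np.maximum(self.array("V"), 0.0) ** (1.0 / 3.0)

    @property
    def total_length(self) -> np.ndarray:
        return self.L / self.params.deltaM

    @property
    def carapace_length(self) -> np.ndarray:
        return self.L / self.params.deltaMC

    @property
    def wet_weights(self) -> np.ndarray:
        return np.array([wet_weight(s, self.params) for s in self.states])

    def to_frame(self):
        """Tidy per-time-point table (one row per node)."""
        import pandas as pd

        rows = {
            "age_d": self.age,
            "E_J": self.array("E"),
            "V_cm3": self.array("V"),
            "EH_J": self.array("EH"),
            "ER_J": self.array("ER"),
            "S": self.array("S"),
            "L_cm": self.L,
            "TL_cm": self.total_length,
            "CL_cm": self.carapace_length,
            "Ww_g": self.wet_weights,
        }
        for name in ("pA", "pC", "pS", "pJ", "pG", "pR"):
            rows[f"{name}_Jd"] = np.array([getattr(f, name) for f in self.fluxes])
        return pd.DataFrame(rows)

    def events_dict(self) -> dict:
        out = {}
        for name, ev in self.events.items():
            out[name] = {
                "age_d": ev.age,
                "L_cm": ev.state.L,
                "E_J": ev.state.E,
                "V_cm3": ev.state.V,
                "EH_J": ev.state.EH,
            }
        return out


_STAGE_THRESHOLDS = (("hatch", "EHh"), ("birth", "EHb"), ("puberty", "EHp"))


def _constant_rhs(params: SpeciesParameters, f: float, cT: float,
                  include_ageing: bool, stage: int):
    """Flat right-hand side for constant forcing (hot path).

    Algebra identical to :func:`state_derivative` with the life stage
    pinned; kept free of dataclass construction because the solver calls
    it thousands of times.
    """
    kappa, EG = params.kappa, params.EG
    pAm, v, pM, kJ = (params.pAm * cT, params.v * cT, params.pM * cT,
                      params.kJ * cT)
    ha2 = params.ha * cT * cT
    sG, Em, Vm = params.sG, params.Em, params.Lm ** 3
    feeding = stage >= 1
    adult = stage == 2

    def rhs(t, y):
        E, V, EH, ER, q, h, S = y
        if V < 0.0:
            V = 0.0
        if E < 0.0:
            E = 0.0
        L = V ** (1.0 / 3.0)
        L2 = L * L
        pS = pM * V
        den = EG * V + kappa * E
        pC = E * (v * EG * L2 + pS) / den if den > 0.0 else 0.0
        pA = pAm * f * L2 if feeding else 0.0
        pG = kappa * pC - pS
        pR = (1.0 - kappa) * pC - kJ * EH
        dq = dh = dS = 0.0
        if include_ageing:
            if feeding and V > 0.0:
                e_sc = E / (V * Em)
                r = pG / (EG * V)
                dq = ((q * (V / Vm) * sG + ha2) * e_sc * (v / L - r) - r * q)
                dh = q - r * h
            dS = -h * (S if S > 0.0 else 0.0)
        return (pA - pC, pG / EG,
                0.0 if adult else pR, pR if adult else 0.0,
                dq, dh, dS)

    return rhs


def integrate_lifecycle(params: SpeciesParameters, environment: Environment,
                        E0: float, horizon: float,
                        n_points: int = 201,
                        V0: float = V_EPSILON,
                        rtol: float = 1e-8,
                        correct_t0: bool = True,
                        include_ageing: bool = True,
                        log_spacing: bool = False,
                        terminate_at: str | None = None,
                        max_rhs_calls: int = 500_000) -> Trajectory:
    """Integrate the life cycle from an egg of reserve ``E0``.

    Starts from (E = E0, V ~ 0, E_H = 0) after the development delay t0
    (temperature-corrected with the same factor as the rates unless
    ``correct_t0`` is off) and detects the hatch/birth/puberty threshold
    crossings with the solver's event localization.  Birth and puberty
    switch the right-hand side (feeding on, maturation rerouted), so the
    integration proceeds in stage segments: the solver stops exactly at
    each switching threshold and restarts with the state clamped onto it,
    keeping every segment discontinuity-free.  ``horizon`` is the maximum
    age (d) from egg laying.  ``terminate_at`` may name a stage to stop the
    integration at its event.

    Raises ``RuntimeError`` if the solver fails or produces non-finite
    state, with the species and forcing in the message.
    """
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    cT0 = environment.ct_at(0.0, params)
    t0_offset = params.t0 / cT0 if correct_t0 else params.t0
    t_end = horizon - t0_offset
    if t_end <= 0:
        raise ValueError("horizon does not exceed the development delay t0")

    constant = (not callable(environment.temperature)
                and not callable(environment.f)
                and not callable(environment.X))

    # degenerate parameter sets can drive the solver into astronomically
    # many micro-steps (e.g. structure collapsing onto V = 0); bound the
    # work and report failure instead of stalling
    ncalls = [0]

    def stage_rhs(stage: int):
        if constant:
            base = _constant_rhs(params, environment.f_at(0.0, params), cT0,
                                 include_ageing, stage)
        else:
            def base(t, y):
                st = OrganismState(*y)
                age = t + t0_offset
                cT = environment.ct_at(age, params)
                f = environment.f_at(age, params)
                d = state_derivative(st, params, f, cT, stage=stage)
                if not include_ageing:
                    d = replace(d, q=0.0, h=0.0, S=0.0)
                return [d.E, d.V, d.EH, d.ER, d.q, d.h, d.S]

        def rhs(t, y):
            ncalls[0] += 1
            if ncalls[0] > max_rhs_calls:
                raise RuntimeError(
                    f"life-cycle integration exceeded {max_rhs_calls} "
                    f"derivative evaluations for {params.species} "
                    f"({params.sex})"
                )
            return base(t, y)

        return rhs

    def threshold_event(attr: str, terminal: bool):
        def ev(t, y, thr=getattr(params, attr)):
            return y[2] - thr
        ev.direction = 1
        ev.terminal = terminal
        return ev

    y0 = np.array([E0, V0, 0.0, 0.0, 0.0, 0.0, 1.0])
    atol = [rtol * E0, 1e-14, rtol * params.EHp, rtol * params.EHp, 1e-16, 1e-14, 1e-10]
    if log_spacing:
        # dense nodes early (embryo/juvenile growth), sparse at the asymptote
        t_eval = np.concatenate(
            ([0.0], np.geomspace(max(1e-3, 1e-4 * t_end), t_end, n_points - 1))
        )
    else:
        t_eval = np.linspace(0.0, t_end, n_points)

    # stage segments: embryo (until E_H = E_H^b), juvenile (until E_H^p),
    # adult; the right-hand side switches at the segment boundaries
    evs: dict[str, StageEvent] = {}
    t_nodes: list[np.ndarray] = []
    y_nodes: list[np.ndarray] = []
    t_cur, y_cur = 0.0, y0
    segments = ((0, "birth", "EHb"), (1, "puberty", "EHp"), (2, None, None))
    for stage, boundary, attr in segments:
        if t_cur >= t_end:
            break
        seg_events = []
        if boundary == "birth":  # hatching falls inside the embryo segment
            seg_events.append(threshold_event("EHh", terminal=False))
        if boundary is not None:
            seg_events.append(threshold_event(attr, terminal=True))
        seg_eval = t_eval[(t_eval >= t_cur) & (t_eval <= t_end)]
        sol = solve_ivp(stage_rhs(stage), (t_cur, t_end), y_cur,
                        method="LSODA", t_eval=seg_eval, rtol=rtol,
                        atol=atol, events=seg_events or None)
        if not sol.success:
            raise RuntimeError(
                f"life-cycle integration failed for {params.species} "
                f"({params.sex}): {sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            raise RuntimeError(
                f"non-finite state in life-cycle integration for "
                f"{params.species}"
            )
        t_seg = np.asarray(sol.t, dtype=float)
        if t_seg.size:
            t_nodes.append(t_seg)
            y_nodes.append(np.asarray(sol.y).reshape(len(y0), -1))
        if boundary == "birth" and sol.t_events[0].size:
            evs["hatch"] = StageEvent(
                name="hatch", age=sol.t_events[0][0] + t0_offset,
                state=OrganismState(*sol.y_events[0][0]),
            )
        if boundary is None or not sol.t_events[-1].size:
            break  # horizon reached before the next stage switch
        te, ye = sol.t_events[-1][0], sol.y_events[-1][0].copy()
        ye[2] = getattr(params, attr)  # clamp exactly onto the threshold
        evs[boundary] = StageEvent(name=boundary, age=te + t0_offset,
                                   state=OrganismState(*ye))
        if boundary == terminate_at:
            break
        t_cur, y_cur = te, ye
    if terminate_at == "hatch" and "hatch" in evs:
        # hatching does not switch the dynamics; honour termination by
        # truncating the assembled nodes
        cut = evs["hatch"].age - t0_offset
        t_nodes = [t[t <= cut] for t in t_nodes]
        y_nodes = [y[:, :len(t)] for t, y in zip(t_nodes, y_nodes)]

    t_all = np.concatenate(t_nodes) if t_nodes else np.array([0.0])
    y_all = (np.concatenate(y_nodes, axis=1) if t_nodes
             else y0.reshape(-1, 1))
    # segment boundaries duplicate grid nodes only if a node coincides with
    # an event time; drop exact duplicates
    keep = np.concatenate(([True], np.diff(t_all) > 0))
    t_all, y_all = t_all[keep], y_all[:, keep]

    ages = t_all + t0_offset
    states = [OrganismState(*y_all[:, i]) for i in range(y_all.shape[1])]
    fluxes = []
    for age, st in zip(ages, states):
        cT = environment.ct_at(age, params)
        f = environment.f_at(age, params)
        fluxes.append(metabolic_fluxes(st, params, f, cT))
    return Trajectory(params=params, age=ages, states=states, fluxes=fluxes,
                      events=evs, t0_offset=t0_offset, success=True)
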