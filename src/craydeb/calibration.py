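"""Simplified weighted relative-error calibration and goodness of fit.

Fits a chosen subset of DEB parameters to an :class:`ObservationSet` by
minimizing the weighted squared relative error with a derivative-free
simplex search, and reports the mean relative error (MRE) and symmetric
mean squared error (SMSE) goodness-of-fit measures.

This is deliberately a simplified stand-in for the full covariation
estimation machinery used to produce the shipped parameter sets (which adds
pseudo-data, an augmented loss and parameter filters).  The weighted
relative-error loss keeps the same spirit, so MRE-style comparisons remain
meaningful, but fits here are meant for recovery experiments on synthetic
data, not for re-estimating published parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import temperature_correction, wet_weight, OrganismState
from .life_history import (
    equilibrium_mobilization,
    initial_reserve,
    mean_lifespan,
    reference_trajectory,
    stage_events,
    ultimate_structural_length,
    ultimate_total_length,
    max_reproduction_rate,
)
from .species import SpeciesParameters, validate
from .synthetic import ObservationSet

__all__ = [
    "FitResult",
    "predict_observations",
    "goodness_of_fit",
    "fit_parameters",
    "FREE_PARAMETER_CHOICES",
]

#: Continuous parameters eligible for fitting.
FREE_PARAMETER_CHOICES = (
    "pAm", "v", "kappa", "pM", "EG", "EHh", "EHb", "EHp", "ha", "t0",
    "deltaM", "deltaMC", "kJ", "kapR",
)


# ---------------------------------------------------------------------------
# forward predictions aligned to an observation set
# ---------------------------------------------------------------------------

class _PredictionCache:
    """Per-call cache: egg energies and reference trajectories keyed by f.

    ``fast=True`` (used inside the simplex loop) relaxes solver tolerances
    and shortens the trajectory horizon; the induced prediction error is
    orders of magnitude below the recovery tolerances it supports.
    """

    def __init__(self, params: SpeciesParameters, fast: bool = False):
        self.params = params
        self.rtol = 1e-6 if fast else 1e-8
        self.horizon = 8_000.0 if fast else None
        self._E0: dict[float, float] = {}
        self._traj: dict[float, object] = {}

    def E0(self, f: float) -> float:
        if f not in self._E0:
            self._E0[f] = initial_reserve(self.params, f, rtol=self.rtol)
        return self._E0[f]

    def traj(self, f: float):
        if f not in self._traj:
            kw = {} if self.horizon is None else {"horizon": self.horizon}
            self._traj[f] = reference_trajectory(
                self.params, f, n_points=400, E0=self.E0(f),
                include_ageing=False, log_spacing=True,
                rtol=max(1e-8, 0.1 * self.rtol),
                max_rhs_calls=100_000 if self.horizon else 500_000, **kw,
            )
        return self._traj[f]


def _fecundity_at_length(params: SpeciesParameters, TL, f: float,
                         cT: float, E0: float) -> np.ndarray:
    """Eggs per clutch at total length TL: annual output at that size under
    the species' clutch schedule.  Clamped at zero below the reproductive
    size."""
    L = np.asarray(TL, dtype=float) * params.deltaM
    pC = equilibrium_mobilization(params, L, f)
    pR = (1.0 - params.kappa) * pC - params.kJ * params.EHp
    annual = 365.0 * cT * params.kapR * np.maximum(pR, 0.0) / E0
    return annual / params.clutches_per_year


def _zero_variate_value(params: SpeciesParameters, name: str, f: float,
                        T: float, correction: str, cache: _PredictionCache):
    if name == "ultimate_total_length":
        return ultimate_total_length(params, f)
    if name == "ultimate_carapace_length":
        return ultimate_structural_length(params, f) / params.deltaMC
    if name == "egg_energy":
        return cache.E0(f)
    if name == "max_reproduction_rate":
        return max_reproduction_rate(params, f, T, correction, E0=cache.E0(f))
    if name == "mean_lifespan":
        return mean_lifespan(params, f, T, correction)
    if name == "ultimate_wet_weight":
        L = ultimate_structural_length(params, f)
        st = OrganismState(E=f * params.Em * L**3, V=L**3, EH=params.EHp)
        return wet_weight(st, params)

    stage_names = {"hatching": "hatch", "birth": "birth", "puberty": "puberty"}
    for key, stage in stage_names.items():
        if name.endswith(key):
            traj = cache.traj(f)
            ev = traj.events.get(stage)
            if ev is None:
                return math.nan
            if name.startswith("age"):
                cT = temperature_correction(T, params, correction)
                return (params.t0 + (ev.age - traj.t0_offset)) / cT
            if name.startswith("total_length"):
                shape = params.deltaM
                if stage == "hatch" and params.deltaMh:
                    shape = params.deltaMh
                return ev.state.L / shape
            if name.startswith("carapace_length"):
                return ev.state.L / params.deltaMC
            if name.startswith("wet_weight"):
                return wet_weight(ev.state, params)
    raise KeyError(f"unknown zero-variate trait {name!r}")


def _uni_variate_values(params: SpeciesParameters, u, correction: str,
                        cache: _PredictionCache) -> np.ndarray:
    cT = temperature_correction(u.temp_K, params, correction)
    traj = cache.traj(u.f)
    t_ref = traj.age - traj.t0_offset
    if u.kind in ("time_length", "time_weight"):
        # age at T (from egg laying) -> reference-temperature clock
        tau = np.clip(np.asarray(u.x, dtype=float) * cT - params.t0, 0.0, None)
        if u.kind == "time_length":
            return np.interp(tau, t_ref, traj.total_length)
        return np.interp(tau, t_ref, traj.wet_weights)
    if u.kind == "length_weight":
        return np.interp(u.x, traj.total_length, traj.wet_weights)
    if u.kind == "length_fecundity":
        return _fecundity_at_length(params, u.x, u.f, cT, cache.E0(u.f))
    raise KeyError(f"unknown uni-variate kind {u.kind!r}")


def predict_observations(params: SpeciesParameters, design: ObservationSet,
                         correction: str = "one_parameter",
                         fast: bool = False):
    """Model predictions aligned to an observation set (or design).

    Returns ``(zero_values, uni_value_arrays)`` in record order; each
    record is evaluated at its own temperature and food level.  Unreached
    stages yield NaN for the affected records.  Predictions do not depend
    on record ordering.
    """
    cache = _PredictionCache(params, fast=fast)
    zvals = [
        _zero_variate_value(params, z.name, z.f, z.temp_K, correction, cache)
        for z in design.zero
    ]
    uvals = [_uni_variate_values(params, u, correction, cache)
             for u in design.uni]
    return zvals, uvals


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def _flatten(obs: ObservationSet, zpred, upred):
    o, p, w = [], [], []
    for z, zp in zip(obs.zero, zpred):
        o.append(z.value)
        p.append(zp)
        w.append(z.weight)
    for u, up in zip(obs.uni, upred):
        n = len(u.x)
        o.extend(np.asarray(u.y, dtype=float))
        p.extend(np.asarray(up, dtype=float))
        w.extend([u.weight / n] * n)
    return np.asarray(o, float), np.asarray(p, float), np.asarray(w, float)


def goodness_of_fit(obs, pred, weights=None) -> tuple[float, float]:
    """Weighted MRE and SMSE between observations and predictions.

    MRE is the weighted mean of |pred - obs|/|obs| (0 = perfect fit,
    unbounded above for arbitrarily poor predictions, despite the nominal
    [0, 1] description in the estimation literature).  SMSE is the weighted
    mean of (pred - obs)^2/(pred^2 + obs^2), a symmetric measure bounded in
    [0, 1].  ``obs`` and ``pred`` may be flat arrays, or ``obs`` an
    :class:`ObservationSet` with ``pred`` the matching prediction pair.
    """
    if isinstance(obs, ObservationSet):
        obs_v, pred_v, w = _flatten(obs, *pred)
    else:
        obs_v = np.asarray(obs, float)
        pred_v = np.asarray(pred, float)
        w = (np.ones_like(obs_v) if weights is None
             else np.asarray(weights, float))
    if np.any(obs_v == 0):
        raise ValueError("observations must be non-zero for relative errors")
    ok = np.isfinite(pred_v)
    obs_v, pred_v, w = obs_v[ok], pred_v[ok], w[ok]
    wsum = w.sum()
    mre = float(np.sum(w * np.abs(pred_v - obs_v) / np.abs(obs_v)) / wsum)
    smse = float(np.sum(w * (pred_v - obs_v) ** 2
                        / (pred_v ** 2 + obs_v ** 2)) / wsum)
    return mre, smse


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: SpeciesParameters
    free: list[str]
    loss: float
    mre: float
    smse: float
    trace: list = field(default_factory=list)  # (nfev, loss) accepted steps
    converged: bool = False
    nfev: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "free": list(self.free),
            "fitted": {k: getattr(self.params, k) for k in self.free},
            "loss": self.loss,
            "MRE": self.mre,
            "SMSE": self.smse,
            "converged": self.converged,
            "nfev": self.nfev,
            "message": self.message,
        }


_DEFAULT_BOUNDS = {
    "kappa": (0.05, 0.999),
}


def _make_transform(name: str, bounds) -> tuple:
    """Map a bounded parameter to an unconstrained coordinate.

    Log transform for positive parameters, scaled logit where both bounds
    are finite (e.g. kappa), so the simplex can roam freely.
    """
    lo, hi = bounds if bounds else (0.0, math.inf)
    if math.isfinite(hi):
        def fwd(x):
            z = (x - lo) / (hi - lo)
            z = min(max(z, 1e-12), 1 - 1e-12)
            return math.log(z / (1 - z))

        def inv(y):
            return lo + (hi - lo) / (1 + math.exp(-y))
    else:
        def fwd(x):
            return math.log(max(x, 1e-300))

        def inv(y):
            return math.exp(min(y, 690.0))
    return fwd, inv


def fit_parameters(obs: ObservationSet, initial: SpeciesParameters,
                   free: list[str], bounds: dict | None = None,
                   weights=None, correction: str = "one_parameter",
                   maxiter: int = 500, restarts: int = 1,
                   seed: int | None = 0,
                   xatol: float = 1e-6, fatol: float = 1e-10) -> FitResult:
    """Minimize the weighted squared relative error over ``free`` parameters.

    Derivative-free Nelder-Mead simplex in transformed (log / logit)
    coordinates, with ``restarts`` additional seeded restarts from a
    perturbed best point.  Bounds are enforced by the transformation;
    deterministic given the seed.  Non-convergence is flagged on the result
    and the best point is still returned.
    """
    unknown = set(free) - set(FREE_PARAMETER_CHOICES)
    if unknown:
        raise ValueError(f"cannot fit parameters: {sorted(unknown)}")
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    # unstated bounds default to a factor of 10 around the start point,
    # keeping the simplex inside a physiologically meaningful region
    for name in free:
        if name not in bounds:
            x0 = getattr(initial, name)
            bounds[name] = (0.1 * x0, 10.0 * x0)
    transforms = [_make_transform(name, bounds.get(name)) for name in free]

    def unpack(y) -> SpeciesParameters:
        changes = {name: inv(yi)
                   for (name, (_, inv), yi) in zip(free, transforms, y)}
        return initial.replace(**changes)

    trace: list = []
    state = {"nfev": 0, "best": math.inf}

    def loss(y) -> float:
        state["nfev"] += 1
        p = unpack(y)
        if validate(p):
            return 1e6
        try:
            zp, up = predict_observations(p, obs, correction, fast=True)
        except RuntimeError:
            return 1e6
        o, pr, w = _flatten(obs, zp, up)
        ok = np.isfinite(pr)
        if not ok.any():
            return 1e6
        val = float(np.sum(w[ok] * ((pr[ok] - o[ok]) / o[ok]) ** 2)
                    / np.sum(w[ok]))
        # penalize records the candidate cannot predict at all
        val += 10.0 * (len(ok) - ok.sum()) / len(ok)
        if val < state["best"]:
            state["best"] = val
            trace.append((state["nfev"], val))
        return val

    rng = np.random.default_rng(seed)
    y0 = np.array([fwd(getattr(initial, name))
                   for name, (fwd, _) in zip(free, transforms)])
    best = None
    start = y0
    for attempt in range(restarts + 1):
        res = minimize(loss, start, method="Nelder-Mead",
                       options=dict(maxiter=maxiter, xatol=xatol,
                                    fatol=fatol, adaptive=True))
        if best is None or res.fun < best.fun:
            best = res
        if best.fun <= fatol:
            break
        start = best.x + rng.normal(0.0, 0.05, size=best.x.size)

    fitted = unpack(best.x)
    zp, up = predict_observations(fitted, obs, correction)
    mre, smse = goodness_of_fit(obs, (zp, up))
    return FitResult(params=fitted, free=list(free), loss=float(best.fun),
                     mre=mre, smse=smse, trace=trace,
                     converged=bool(best.success), nfev=state["nfev"],
                     message=str(best.message))
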