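"""Pseudo-observation generator for calibration and recovery experiments.

Real DEB parameter estimation consumes two data classes: zero-variate
records (single life-history values such as age at puberty or egg energy,
each at a stated temperature and food level) and uni-variate curves
(time-length, length-weight, length-fecundity, ...).  This module generates
sets with exactly that structure from a known parameter set, perturbed by
multiplicative lognormal noise, so the calibration machinery can be tested
for parameter recovery.  It makes no attempt to reconstruct the literature
datasets behind the shipped species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .species import SpeciesParameters

__all__ = [
    "ZeroVariate",
    "UniVariate",
    "ObservationSet",
    "generate_observations",
    "default_design",
]


@dataclass
class ZeroVariate:
    """One single-valued pseudo-observation (value None in a design)."""

    name: str
    value: float | None
    unit: str
    temp_K: float
    f: float
    weight: float = 1.0


@dataclass
class UniVariate:
    """One pseudo-observed curve; ``y`` is None in a design.

    ``kind`` is one of ``time_length``, ``time_weight``, ``length_weight``,
    ``length_fecundity``.  The total record weight is spread as weight/n
    over the n points so each dataset contributes comparably to a fit.
    """

    kind: str
    x: np.ndarray
    y: np.ndarray | None
    unit_x: str
    unit_y: str
    temp_K: float
    f: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)


@dataclass
class ObservationSet:
    """Zero-variate and uni-variate pseudo-observations plus provenance."""

    zero: list = field(default_factory=list)
    uni: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def n_points(self) -> int:
        return len(self.zero) + sum(len(u.x) for u in self.uni)

    # -- serialization ----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """CSV per record class + JSON manifest with provenance."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.zero:
            pd.DataFrame([asdict(z) for z in self.zero]).to_csv(
                directory / "zero_variate.csv", index=False
            )
        rows = []
        for i, u in enumerate(self.uni):
            for xv, yv in zip(u.x, u.y if u.y is not None else [None] * len(u.x)):
                rows.append(
                    dict(series=i, kind=u.kind, x=xv, y=yv, unit_x=u.unit_x,
                         unit_y=u.unit_y, temp_K=u.temp_K, f=u.f,
                         weight=u.weight)
                )
        if rows:
            pd.DataFrame(rows).to_csv(directory / "uni_variate.csv", index=False)
        (directory / "manifest.json").write_text(
            json.dumps(self.provenance, indent=1, default=float)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ObservationSet":
        directory = Path(directory)
        obs = cls()
        zpath = directory / "zero_variate.csv"
        if zpath.exists():
            for _, r in pd.read_csv(zpath).iterrows():
                obs.zero.append(ZeroVariate(
                    name=r["name"], value=float(r["value"]), unit=r["unit"],
                    temp_K=float(r["temp_K"]), f=float(r["f"]),
                    weight=float(r["weight"]),
                ))
        upath = directory / "uni_variate.csv"
        if upath.exists():
            df = pd.read_csv(upath)
            for _, g in df.groupby("series"):
                first = g.iloc[0]
                obs.uni.append(UniVariate(
                    kind=first["kind"], x=g["x"].to_numpy(),
                    y=g["y"].to_numpy(), unit_x=first["unit_x"],
                    unit_y=first["unit_y"], temp_K=float(first["temp_K"]),
                    f=float(first["f"]), weight=float(first["weight"]),
                ))
        mpath = directory / "manifest.json"
        if mpath.exists():
            obs.provenance = json.loads(mpath.read_text())
        return obs


def default_design(params: SpeciesParameters,
                   f_levels=(0.7, 1.0),
                   temps_K=(285.15, 293.15)) -> ObservationSet:
    """Design mirroring the richest real data layout (signal crayfish):
    growth curves at two temperatures and two food levels, a length-weight
    and a length-fecundity curve, plus the core zero-variate traits."""
    Tt = params.Ttyp
    TL_max = 0.95 * params.kappa * params.pAm / params.pM / params.deltaM
    design = ObservationSet()
    z = design.zero.append
    z(ZeroVariate("ultimate_total_length", None, "cm", Tt, 1.0))
    z(ZeroVariate("total_length_at_puberty", None, "cm", Tt, 1.0))
    z(ZeroVariate("age_at_puberty", None, "d", Tt, 1.0))
    z(ZeroVariate("age_at_birth", None, "d", Tt, 1.0))
    z(ZeroVariate("egg_energy", None, "J", Tt, 1.0))
    z(ZeroVariate("max_reproduction_rate", None, "eggs/d", Tt, 1.0))
    t_grid = np.linspace(100.0, 2500.0, 10)
    for T in temps_K:
        design.uni.append(UniVariate("time_length", t_grid, None, "d", "cm",
                                     T, 1.0))
    for f in f_levels:
        design.uni.append(UniVariate("time_length", t_grid, None, "d", "cm",
                                     Tt, f))
    TL_grid = np.linspace(0.35 * TL_max, TL_max, 8)
    design.uni.append(UniVariate("length_weight", TL_grid, None, "cm", "g",
                                 Tt, 1.0))
    design.uni.append(UniVariate("length_fecundity", TL_grid[3:], None,
                                 "cm", "eggs", Tt, 1.0))
    return design


def generate_observations(true_params: SpeciesParameters,
                          design: ObservationSet | None = None,
                          noise_cv: float = 0.0,
                          seed: int | None = None) -> ObservationSet:
    """Fill a design with model predictions perturbed by lognormal noise.

    Noise is multiplicative with coefficient of variation ``noise_cv`` and
    unit mean, so positivity is preserved and noise-free sets equal the
    model predictions exactly.  Deterministic under a fixed seed.
    """
    from .calibration import predict_observations

    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if design is None:
        design = default_design(true_params)
    if not design.zero and not design.uni:
        raise ValueError("design must contain at least one record")

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))

    def perturb(values):
        if noise_cv == 0.0:
            return np.asarray(values, dtype=float)
        draw = rng.normal(-0.5 * sigma**2, sigma, size=np.shape(values))
        return np.asarray(values) * np.exp(draw)

    zpred, upred = predict_observations(true_params, design)
    out = ObservationSet(provenance={
        "species": true_params.species,
        "sex": true_params.sex,
        "true_params": true_params.to_dict(),
        "noise_cv": noise_cv,
        "seed": seed,
    })
    for z, v in zip(design.zero, zpred):
        out.zero.append(ZeroVariate(z.name, float(perturb(v)), z.unit,
                                    z.temp_K, z.f, z.weight))
    for u, y in zip(design.uni, upred):
        out.uni.append(UniVariate(u.kind, u.x.copy(), perturb(y), u.unit_x,
                                  u.unit_y, u.temp_K, u.f, u.weight))
    return out
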