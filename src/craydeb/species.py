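"""Species parameter registry for the four crayfish DEB models.

Houses the full primary + auxiliary Dynamic Energy Budget parameter set for
each of the two native European species (*Astacus astacus*,
*Austropotamobius torrentium*) and the two invaders (*Pacifastacus
leniusculus*, *Procambarus virginalis*), stored at the reference temperature
293.15 K.  Parameter sets ship as one human-readable YAML file per species
plus a combined JSON file, and round-trip losslessly through both.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "SpeciesParameters",
    "ParameterRegistry",
    "SPECIES_IDS",
    "load_species",
    "validate",
    "get_registry",
]

#: Canonical species identifiers, in the order used throughout the package.
SPECIES_IDS = (
    "austropotamobius_torrentium",
    "astacus_astacus",
    "pacifastacus_leniusculus",
    "procambarus_virginalis",
)

#: Convenience aliases accepted anywhere a species id is expected.
SPECIES_ALIASES = {
    "at": "austropotamobius_torrentium",
    "aa": "astacus_astacus",
    "pl": "pacifastacus_leniusculus",
    "pv": "procambarus_virginalis",
    "stone_crayfish": "austropotamobius_torrentium",
    "noble_crayfish": "astacus_astacus",
    "signal_crayfish": "pacifastacus_leniusculus",
    "marbled_crayfish": "procambarus_virginalis",
}

#: Species without males (obligate parthenogenesis).
PARTHENOGENETIC = ("procambarus_virginalis",)


@dataclass
class SpeciesParameters:
    """One species/sex DEB parameter set, at ``Tref`` = 293.15 K.

    Primary parameters follow standard DEB notation: ``pAm`` is the maximum
    surface-specific assimilation rate {p_Am} (J/d/cm^2), ``v`` the energy
    conductance (cm/d), ``kappa`` the allocation fraction to soma, ``pM`` the
    volume-specific somatic maintenance [p_M] (J/d/cm^3), ``EG`` the specific
    cost of structure [E_G] (J/cm^3).  ``EHh`` < ``EHb`` < ``EHp`` are the
    maturity thresholds (J) for hatching, birth (onset of feeding) and
    puberty (onset of reproduction investment).  ``deltaM``/``deltaMC`` are
    shape coefficients converting structural length V^(1/3) to total and
    carapace length; ``deltaMh`` applies to hatchlings where available.

    Auxiliary parameters (``kJ``, ``kapR``, ``kapX``, ``Fm``, ``sG``) take
    standard DEB defaults where the source parameter tables omit them.
    Composition parameters (``dV``, ``wE``, ``muE``) only affect wet-weight
    output, which is flagged composition-dependent throughout.
    """

    species: str
    sex: str = "female"

    # primary
    pAm: float = 0.0            # J/d/cm^2
    v: float = 0.0              # cm/d
    kappa: float = 0.0          # -
    pM: float = 0.0             # J/d/cm^3
    EG: float = 0.0             # J/cm^3
    EHh: float = 0.0            # J
    EHb: float = 0.0            # J
    EHp: float = 0.0            # J
    ha: float = 0.0             # 1/d^2
    t0: float = 0.0             # d
    deltaM: float = 0.0         # -
    deltaMC: float = 0.0        # -
    deltaMh: float | None = None

    # optional male overlay values (kept for reference on female sets)
    pAm_male: float | None = None
    EHp_male: float | None = None

    # temperature
    TA: float = 8000.0          # K
    TAH: float = 21000.0        # K
    TAL: float = 18000.0        # K
    TH: float = 0.0             # K
    TLcrit: float = 0.0         # K
    Tref: float = 293.15        # K
    Ttyp: float = 293.15        # K

    # auxiliary (standard DEB defaults)
    kJ: float = 0.002           # 1/d
    kapR: float = 0.95          # -
    kapX: float = 0.8           # -
    Fm: float = 6.5             # l/d/cm^2
    sG: float = 0.0             # -

    # composition (wet weight only; composition-dependent outputs)
    dV: float = 1.0             # g/cm^3
    wE: float = 23.9            # g/mol
    muE: float = 93_500.0       # J/mol (effective)

    # presentation-level reproduction convention
    clutches_per_year: float = 1.0

    common_name: str = ""
    family: str = ""

    @property
    def Em(self) -> float:
        """Maximum reserve density [E_m] = {p_Am}/v, J/cm^3."""
        return self.pAm / self.v

    @property
    def Lm(self) -> float:
        """Maximum structural length kappa*{p_Am}/[p_M], cm."""
        return self.kappa * self.pAm / self.pM

    def replace(self, **changes) -> "SpeciesParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


def validate(params: SpeciesParameters) -> list[str]:
    """Check the type invariants of a parameter set.

    Returns a list of human-readable violations (empty when the set is
    valid).  Reports rather than raises, so partially specified sets can be
    inspected during calibration.
    """
    v: list[str] = []
    if not 0.0 < params.kappa < 1.0:
        v.append("kappa out of (0,1)")
    if not 0.0 < params.EHh < params.EHb < params.EHp:
        v.append("maturity thresholds must satisfy 0 < EHh < EHb < EHp")
    for name in ("pAm", "v", "pM", "EG", "kJ", "Fm", "t0",
                 "deltaM", "deltaMC", "TA", "TAH", "TAL"):
        if getattr(params, name) <= 0:
            v.append(f"{name} must be strictly positive")
    for name in ("ha", "sG"):
        if getattr(params, name) < 0:
            v.append(f"{name} must be non-negative")
    if not 0.0 < params.kapR <= 1.0:
        v.append("kapR out of (0,1]")
    if not 0.0 < params.kapX <= 1.0:
        v.append("kapX out of (0,1]")
    if not params.TLcrit < params.Tref < params.TH:
        v.append("temperature boundaries must satisfy TLcrit < Tref < TH")
    if params.dV <= 0 or params.wE <= 0 or params.muE <= 0:
        v.append("composition parameters must be strictly positive")
    return v


def _canonical_id(species_id: str) -> str:
    key = species_id.strip().lower().replace(" ", "_")
    key = SPECIES_ALIASES.get(key, key)
    if key not in SPECIES_IDS:
        raise KeyError(
            f"unknown species {species_id!r}; expected one of {list(SPECIES_IDS)}"
        )
    return key


class ParameterRegistry:
    """Mapping species id -> female parameter set (+ male overlay).

    The shipped registry contains exactly the four study species; extra sets
    can be registered for calibration experiments.
    """

    def __init__(self) -> None:
        self._female: dict[str, SpeciesParameters] = {}
        self._male_overlay: dict[str, dict] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_package_data(cls) -> "ParameterRegistry":
        reg = cls()
        for sid in SPECIES_IDS:
            text = (
                resources.files("craydeb.data").joinpath(f"{sid}.yaml").read_text()
            )
            reg.register_yaml_dict(yaml.safe_load(text))
        return reg

    def register_yaml_dict(self, doc: dict) -> None:
        sid = doc["species"]
        male = doc.get("male") or None
        d = dict(doc["primary"])
        d.update(doc["temperature"])
        d.update(doc["auxiliary"])
        d.update(doc["composition"])
        d.update(doc.get("reproduction", {}))
        d["species"] = sid
        d["sex"] = "female"
        d["common_name"] = doc.get("common_name", "")
        d["family"] = doc.get("family", "")
        if male:
            d["pAm_male"] = male.get("pAm")
            d["EHp_male"] = male.get("EHp")
        self._female[sid] = SpeciesParameters.from_dict(d)
        self._male_overlay[sid] = dict(male) if male else {}

    # -- access -----------------------------------------------------------

    def species_ids(self) -> tuple[str, ...]:
        return tuple(self._female)

    def load(self, species_id: str, sex: str = "female") -> SpeciesParameters:
        sid = _canonical_id(species_id)
        if sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
        base = self._female[sid]
        if sex == "female":
            return base.replace()
        if sid in PARTHENOGENETIC or not self._male_overlay.get(sid):
            raise ValueError(
                f"{sid} is obligately parthenogenetic: no male parameter set"
            )
        ov = self._male_overlay[sid]
        # the male overlay replaces the assimilation rate and puberty
        # threshold only; everything else is shared with females
        return base.replace(sex="male", pAm=ov["pAm"], EHp=ov["EHp"])

    # -- serialization ----------------------------------------------------

    def to_yaml_dict(self, species_id: str) -> dict:
        sid = _canonical_id(species_id)
        p = self._female[sid]
        doc = {
            "species": sid,
            "common_name": p.common_name,
            "family": p.family,
            "primary": {
                k: getattr(p, k)
                for k in ("pAm", "v", "kappa", "pM", "EG", "EHh", "EHb",
                          "EHp", "ha", "t0", "deltaM", "deltaMC", "deltaMh")
            },
            "male": dict(self._male_overlay[sid]) or None,
            "temperature": {
                k: getattr(p, k)
                for k in ("TA", "TAH", "TAL", "TH", "TLcrit", "Tref", "Ttyp")
            },
            "auxiliary": {
                k: getattr(p, k) for k in ("kJ", "kapR", "kapX", "Fm", "sG")
            },
            "composition": {k: getattr(p, k) for k in ("dV", "wE", "muE")},
            "reproduction": {"clutches_per_year": p.clutches_per_year},
        }
        return doc

    def save(self, directory: str | Path) -> None:
        """Write one YAML per species plus a combined ``species.json``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        combined = {}
        for sid in self.species_ids():
            doc = self.to_yaml_dict(sid)
            (directory / f"{sid}.yaml").write_text(
                yaml.safe_dump(doc, sort_keys=False)
            )
            combined[sid] = doc
        (directory / "species.json").write_text(json.dumps(combined, indent=1))

    @classmethod
    def from_directory(cls, directory: str | Path) -> "ParameterRegistry":
        reg = cls()
        for path in sorted(Path(directory).glob("*.yaml")):
            reg.register_yaml_dict(yaml.safe_load(path.read_text()))
        return reg


_REGISTRY: ParameterRegistry | None = None


def get_registry() -> ParameterRegistry:
    """Shared registry built from the shipped parameter files."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = ParameterRegistry.from_package_data()
    return _REGISTRY


def load_species(species_id: str, sex: str = "female") -> SpeciesParameters:
    """Load a shipped parameter set.

    Parameters
    ----------
    species_id
        Canonical id (e.g. ``"astacus_astacus"``) or an alias (``"aa"``,
        ``"noble_crayfish"``).
    sex
        ``"female"`` (default) or ``"male"``.  The male overlay replaces the
        assimilation rate and the puberty maturity threshold only.
        Requesting a male *P. virginalis* raises (parthenogenetic species).
    """
    return get_registry().load(species_id, sex)
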