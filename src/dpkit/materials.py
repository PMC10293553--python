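"""Material compositions and effective atomic number/weight.

The built-in registry holds two material sets commonly used for dose
point kernel work:

* a *training* set of 23 materials obtained from a Schneider-style
  stoichiometric CT calibration, each labelled by the Hounsfield-unit
  bin it represents (``HU-950`` … ``HU1600``), and
* a *testing* set of 4 reference tissues (air, lung, soft tissue,
  cortical bone) following ICRP reference-person compositions.

Compositions are elemental weight fractions over a fixed 12-element set
(H, C, N, O, Na, Mg, P, S, Cl, Ar, K, Ca) plus a mass density in g/cm³.
Materials containing other elements cannot be registered; this is a
documented limitation of the feature design downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "ELEMENT_ORDER",
    "ELEMENT_Z",
    "ELEMENT_A",
    "MaterialSpec",
    "EffectiveZA",
    "material_lookup",
    "register_material",
    "training_labels",
    "testing_labels",
    "all_labels",
    "effective_za",
]

#: Fixed element order used everywhere (compositions, feature vectors).
ELEMENT_ORDER = ("H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "Ar", "K", "Ca")

ELEMENT_Z: Mapping[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Mg": 12,
    "P": 15, "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20,
}

#: Standard atomic weights, g/mol.
ELEMENT_A: Mapping[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "Na": 22.98976928, "Mg": 24.305, "P": 30.973761998, "S": 32.06,
    "Cl": 35.45, "Ar": 39.948, "K": 39.0983, "Ca": 40.078,
}


@dataclass(frozen=True)
class MaterialSpec:
    """A homogeneous material: elemental weight fractions and density.

    Weight fractions may sum to slightly less/more than 1 because the
    source tables are rounded; the allowed window is [0.98, 1.02].
    """

    label: str
    weight_fractions: Mapping[str, float]
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        unknown = set(self.weight_fractions) - set(ELEMENT_ORDER)
        if unknown:
            raise ValueError(
                f"material {self.label!r} uses unsupported elements {sorted(unknown)}; "
                f"supported set is {ELEMENT_ORDER}"
            )
        fracs = dict(self.weight_fractions)
        if any(v < 0 for v in fracs.values()):
            raise ValueError(f"material {self.label!r} has negative weight fractions")
        total = sum(fracs.values())
        if not (0.98 <= total <= 1.02):
            raise ValueError(
                f"material {self.label!r}: weight fractions sum to {total:.4f}, "
                "outside [0.98, 1.02]"
            )
        if not self.density > 0:
            raise ValueError(f"material {self.label!r}: density must be positive")
        object.__setattr__(self, "weight_fractions", fracs)

    def fraction(self, element: str) -> float:
        return self.weight_fractions.get(element, 0.0)


@dataclass(frozen=True)
class EffectiveZA:
    """Effective atomic number and weight of a compound."""

    z_eff: float
    a_eff: float  # g/mol


def _load_builtin() -> tuple[dict[str, MaterialSpec], dict[str, str]]:
    registry: dict[str, MaterialSpec] = {}
    sets: dict[str, str] = {}
    text = resources.files("dpkit.data").joinpath("materials.csv").read_text()
    for row in csv.DictReader(text.splitlines()):
        fracs = {
            el: float(row[el]) for el in ELEMENT_ORDER if row[el] and float(row[el]) > 0
        }
        spec = MaterialSpec(row["label"], fracs, float(row["density"]))
        registry[spec.label] = spec
        sets[spec.label] = row["set"]
    return registry, sets


_REGISTRY, _SETS = _load_builtin()


def material_lookup(label: str) -> MaterialSpec:
    """Return the registered material for ``label``.

    Raises ``KeyError`` naming the available labels if unknown.
    """
    try:
        return _REGISTRY[label]
    except KeyError:
        raise KeyError(
            f"unknown material {label!r}; available: {', '.join(sorted(_REGISTRY))}"
        ) from None


def register_material(spec: MaterialSpec, *, overwrite: bool = False) -> None:
    """Add a user material to the registry (element set is fixed)."""
    if spec.label in _REGISTRY and not overwrite:
        raise ValueError(f"material {spec.label!r} already registered")
    _REGISTRY[spec.label] = spec
    _SETS[spec.label] = "user"


def training_labels() -> list[str]:
    return [lab for lab, s in _SETS.items() if s == "training"]


def testing_labels() -> list[str]:
    return [lab for lab, s in _SETS.items() if s == "testing"]


def all_labels() -> list[str]:
    return list(_REGISTRY)


def effective_za(material: MaterialSpec) -> EffectiveZA:
    """Effective Z and A by electron-fraction (Tabata compound rule) weighting.

    Z_eff = Σ w_i (Z_i/A_i) Z_i / Σ w_i (Z_i/A_i), A_eff = Z_eff / Σ w_i (Z_i/A_i).
    For a single element this returns that element's Z and A exactly.
    """
    num = 0.0
    den = 0.0
    for el, w in material.weight_fractions.items():
        za = ELEMENT_Z[el] / ELEMENT_A[el]
        num += w * za * ELEMENT_Z[el]
        den += w * za
    if den <= 0.0:
        raise ValueError("material has no electrons (all-zero weight fractions)")
    z_eff = num / den
    return EffectiveZA(z_eff=z_eff, a_eff=z_eff / den)
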