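"""Solution-condition (cocktail) featurization.

A raw cocktail is a pH plus molar concentrations of up to 56 chemical
species (19 cations, 24 anions, 13 PEGs). Four derived descriptors
summarise its physical chemistry:

* ``IS``  — ionic strength, ½ Σ c_i z_i² over ionic species (M).
* ``HS+``/``HS-`` — Hofmeister coefficients: concentration-weighted sums of
  a per-ion index h_i that maps the kosmotropic→chaotropic ranking linearly
  onto [+1, −1] (cations and anions ranked separately). Ions without a
  printed rank contribute 0 (the midpoint) and trigger a warning.
* ``DEP`` — depletion-attraction coefficient from PEG excluded volume, the
  Asakura–Oosawa overlap form Σ c_a (1 + R_dep/Rg)³ with the depletant
  radius following Flory scaling R_dep = r0 (M_a / M0)^0.588.

The full cocktail feature vector has 61 entries: 56 species molarities,
pH, IS, HS+, HS- and DEP.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "Species",
    "SpeciesRegistry",
    "build_registry",
    "ionic_strength",
    "hofmeister_coefficients",
    "depletion_coefficient",
    "cocktail_feature_vector",
    "cocktail_feature_names",
    "DERIVED_FEATURES",
]

logger = logging.getLogger(__name__)

DERIVED_FEATURES = ("pH", "IS", "HS+", "HS-", "DEP")

# Flory-scaled PEG depletant radius: R_dep = R0_ANGSTROM * (M / M0)^FLORY_EXPONENT
FLORY_EXPONENT = 0.588
R0_ANGSTROM = 7.0      # depletant radius of the reference PEG (Å)
M0_REFERENCE = 1000.0  # reference PEG molecular mass (g/mol)


@dataclass(frozen=True)
class Species:
    name: str
    kind: str                      # cation | anion | PEG
    charge: int
    hofmeister_rank: int | None    # 1 = most kosmotropic within its kind
    peg_mass: float | None         # g/mol, PEG only


@dataclass(frozen=True)
class SpeciesRegistry:
    entries: tuple[Species, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def names(self, kind: str | None = None) -> list[str]:
        return [s.name for s in self.entries if kind is None or s.kind == kind]

    def get(self, name: str) -> Species:
        for s in self.entries:
            if s.name == name:
                return s
        raise KeyError(f"unknown species {name!r}")

    def hofmeister_index(self, species: Species) -> float | None:
        """h ∈ [+1, −1]: +1 most kosmotropic, −1 most chaotropic of its kind."""
        if species.hofmeister_rank is None:
            return None
        ranks = [
            s.hofmeister_rank
            for s in self.entries
            if s.kind == species.kind and s.hofmeister_rank is not None
        ]
        lo, hi = min(ranks), max(ranks)
        if hi == lo:
            return 0.0
        return 1.0 - 2.0 * (species.hofmeister_rank - lo) / (hi - lo)


@lru_cache(maxsize=1)
def build_registry() -> SpeciesRegistry:
    """The fixed registry of the 56 analysed chemical species."""
    text = resources.files("crystalgp.data").joinpath("species_registry.csv").read_text()
    entries = []
    for row in csv.DictReader(text.splitlines()):
        entries.append(
            Species(
                name=row["name"],
                kind=row["kind"],
                charge=int(row["charge"]),
                hofmeister_rank=int(row["hofmeister_rank"]) if row["hofmeister_rank"] else None,
                peg_mass=float(row["peg_mass"]) if row["peg_mass"] else None,
            )
        )
    return SpeciesRegistry(tuple(entries))


def cocktail_feature_names() -> list[str]:
    """The 61 cocktail feature names in stable column order."""
    return build_registry().names() + list(DERIVED_FEATURES)


def _validate(concentrations: Mapping[str, float]) -> None:
    reg = build_registry()
    known = set(reg.names())
    for name, c in concentrations.items():
        if name not in known:
            raise KeyError(f"unknown species {name!r} in cocktail")
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}: {c}")


def ionic_strength(concentrations: Mapping[str, float]) -> float:
    """IS = ½ Σ c_i z_i² over ionic species, in M (PEGs excluded)."""
    _validate(concentrations)
    reg = build_registry()
    return 0.5 * sum(
        c * reg.get(name).charge ** 2
        for name, c in concentrations.items()
        if reg.get(name).kind in ("cation", "anion")
    )


_warned_unranked: set[str] = set()


def hofmeister_coefficients(concentrations: Mapping[str, float]) -> tuple[float, float]:
    """(HS+, HS-): concentration-weighted Hofmeister sums for cations / anions."""
    _validate(concentrations)
    reg = build_registry()
    hs = {"cation": 0.0, "anion": 0.0}
    for name, c in concentrations.items():
        sp = reg.get(name)
        if sp.kind == "PEG" or c == 0.0:
            continue
        h = reg.hofmeister_index(sp)
        if h is None:
            if name not in _warned_unranked:
                _warned_unranked.add(name)
                logger.warning("species %r has no Hofmeister rank; contributes 0", name)
            continue
        hs[sp.kind] += c * h
    return hs["cation"], hs["anion"]


def depletion_radius(peg_mass: float) -> float:
    """Flory-scaled depletant radius (Å) for a PEG of mass ``peg_mass`` g/mol."""
    return R0_ANGSTROM * (peg_mass / M0_REFERENCE) ** FLORY_EXPONENT


def depletion_coefficient(concentrations: Mapping[str, float], rg: float) -> float:
    """Asakura–Oosawa depletion coefficient Σ_PEG c_a (1 + R_dep,a / Rg)³."""
    if rg <= 0:
        raise ValueError("protein radius of gyration must be positive")
    _validate(concentrations)
    reg = build_registry()
    dep = 0.0
    for name, c in concentrations.items():
        sp = reg.get(name)
        if sp.kind == "PEG" and c > 0:
            dep += c * (1.0 + depletion_radius(sp.peg_mass) / rg) ** 3
    return dep


def peg_percent_mass_to_molarity(percent_mass: float, peg_mass: float) -> float:
    """Convert a PEG % (w/v) concentration to molarity (10 g/L per %)."""
    return percent_mass * 10.0 / peg_mass


def cocktail_feature_vector(
    concentrations: Mapping[str, float], ph: float, rg: float
) -> pd.Series:
    """Full 61-entry cocktail feature vector (species in registry order + derived)."""
    _validate(concentrations)
    reg = build_registry()
    vec = pd.Series(0.0, index=cocktail_feature_names())
    for name, c in concentrations.items():
        vec[name] = c
    vec["pH"] = ph
    vec["IS"] = ionic_strength(concentrations)
    vec["HS+"], vec["HS-"] = hofmeister_coefficients(concentrations)
    vec["DEP"] = depletion_coefficient(concentrations, rg)
    return vec
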