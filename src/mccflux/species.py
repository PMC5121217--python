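"""Chemical bookkeeping for COD-basis carboxylate accounting.

Chain-elongation studies report substrates and products in oxygen
equivalents (g COD) so that ethanol, short-chain carboxylates (SCCs) and
medium-chain carboxylates (MCCs) can be balanced against each other.  This
module holds the species registry (elemental composition, molar mass,
theoretical oxygen demand, pKa), the unit conversions between g/L, mol/L
and g COD/L, and the acid/base speciation used to compute undissociated
carboxylic-acid concentrations at reactor pH.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CarboxylateSpecies",
    "SpeciesRegistry",
    "InvalidCompositionError",
    "UnknownSpeciesError",
    "thod",
    "to_cod",
    "from_cod",
    "undissociated_fraction",
    "default_registry",
]


class InvalidCompositionError(ValueError):
    """Raised for a chemically impossible elemental composition."""


class UnknownSpeciesError(KeyError):
    """Raised when a species name cannot be resolved in the registry."""


def thod(n_c: int, n_h: int, n_o: int) -> float:
    """Theoretical oxygen demand of CnHmOp in g O2 per mole.

    Full oxidation to CO2 and H2O consumes ``n_c + n_h/4 - n_o/2`` moles of
    O2, i.e. ``32 * (n_c + n_h/4 - n_o/2)`` g O2/mol.  Evaluated with exact
    rational arithmetic so registry constants are bit-stable.

    Parameters
    ----------
    n_c, n_h, n_o : int
        Atom counts; must be nonnegative integers with at least one atom.
    """
    for label, n in (("C", n_c), ("H", n_h), ("O", n_o)):
        if not isinstance(n, int) or isinstance(n, bool):
            raise InvalidCompositionError(f"atom count n_{label}={n!r} is not an integer")
        if n < 0:
            raise InvalidCompositionError(f"negative atom count n_{label}={n}")
    if n_c + n_h + n_o == 0:
        raise InvalidCompositionError("empty molecule")
    return float(32 * (Fraction(n_c) + Fraction(n_h, 4) - Fraction(n_o, 2)))


def undissociated_fraction(ph: float, pka: float) -> float:
    """Fraction of a monoprotic acid present in the undissociated form.

    Henderson–Hasselbalch speciation: ``1 / (1 + 10**(pH - pKa))``.  Only the
    undissociated (hydrophobic) acid crosses the pertraction membrane, so
    broth COD concentrations are multiplied by this fraction before any
    mass-transfer calculation.
    """
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


@dataclass(frozen=True)
class CarboxylateSpecies:
    """One registered compound: composition, molar mass and acidity.

    ``cod_factor`` (g COD/mol) is always the ThOD of the composition — the
    oxygen demand of the dissociated carboxylate and the free acid are equal
    because H+ carries no oxygen demand.  ``pka`` is None for non-acids
    (ethanol).  Molar masses refer to the free acid.
    """

    name: str
    n_c: int
    n_h: int
    n_o: int
    molar_mass: float
    carbon_number: int
    pka: Optional[float] = None

    @property
    def cod_factor(self) -> float:
        """g COD per mole, from the ThOD identity."""
        return thod(self.n_c, self.n_h, self.n_o)


def _normalize(name: str) -> str:
    key = name.strip().lower().replace("_", "-").replace(" ", "-")
    while "--" in key:
        key = key.replace("--", "-")
    if key.startswith("n-"):
        key = key[2:]
    return key


class SpeciesRegistry:
    """Alias-tolerant lookup of :class:`CarboxylateSpecies` by name.

    Lookup is case-insensitive and resolves common synonyms ("C8",
    "n-caprylate", "n-caprylic acid", "octanoate" are the same compound).
    """

    def __init__(self) -> None:
        self._species: dict[str, CarboxylateSpecies] = {}
        self._aliases: dict[str, str] = {}

    def register(self, species: CarboxylateSpecies, aliases: Iterable[str] = ()) -> None:
        if species.name in self._species:
            raise ValueError(f"species {species.name!r} already registered")
        self._species[species.name] = species
        for alias in (species.name, *aliases):
            key = _normalize(alias)
            if key in self._aliases and self._aliases[key] != species.name:
                raise ValueError(
                    f"alias {alias!r} collides: {self._aliases[key]!r} vs {species.name!r}"
                )
            self._aliases[key] = species.name

    def get(self, name: str) -> CarboxylateSpecies:
        try:
            return self._species[self._aliases[_normalize(name)]]
        except KeyError:
            raise UnknownSpeciesError(f"unknown species {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return _normalize(name) in self._aliases

    def __iter__(self):
        return iter(self._species.values())

    def __len__(self) -> int:
        return len(self._species)

    @property
    def names(self) -> list[str]:
        return list(self._species)

    def canonical_name(self, name: str) -> str:
        return self.get(name).name

    def to_frame(self) -> pd.DataFrame:
        """Flat-table form (one row per species), suitable for CSV export."""
        rows = [
            {
                "name": s.name,
                "n_C": s.n_c,
                "n_H": s.n_h,
                "n_O": s.n_o,
                "molar_mass": s.molar_mass,
                "cod_factor": s.cod_factor,
                "pKa": s.pka,
                "carbon_number": s.carbon_number,
            }
            for s in self
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, aliases: Optional[dict] = None) -> "SpeciesRegistry":
        reg = cls()
        for _, row in frame.iterrows():
            pka = row.get("pKa")
            species = CarboxylateSpecies(
                name=str(row["name"]),
                n_c=int(row["n_C"]),
                n_h=int(row["n_H"]),
                n_o=int(row["n_O"]),
                molar_mass=float(row["molar_mass"]),
                carbon_number=int(row["carbon_number"]),
                pka=None if pd.isna(pka) else float(pka),
            )
            if "cod_factor" in row and not pd.isna(row["cod_factor"]):
                if abs(species.cod_factor - float(row["cod_factor"])) > 1e-9:
                    raise InvalidCompositionError(
                        f"{species.name}: stated cod_factor {row['cod_factor']} "
                        f"inconsistent with composition (ThOD {species.cod_factor})"
                    )
            reg.register(species, (aliases or {}).get(species.name, ()))
        return reg

    @classmethod
    def from_csv(cls, path, aliases: Optional[dict] = None) -> "SpeciesRegistry":
        return cls.from_frame(pd.read_csv(path), aliases)


# Literature pKa values at 25 degC (no temperature / ionic-strength correction);
# molar masses of the free acids.
_DEFAULTS = [
    # name, n_C, n_H, n_O, molar mass, carbon number, pKa, aliases
    ("ethanol", 2, 6, 1, 46.07, 2, None, ("etoh", "ethyl alcohol")),
    ("acetate", 2, 4, 2, 60.05, 2, 4.76, ("acetic acid", "c2")),
    ("propionate", 3, 6, 2, 74.08, 3, 4.87, ("propionic acid", "c3")),
    ("n-butyrate", 4, 8, 2, 88.11, 4, 4.82, ("butyric acid", "c4", "butanoate")),
    ("n-valerate", 5, 10, 2, 102.13, 5, 4.84, ("valeric acid", "c5", "pentanoate")),
    ("n-caproate", 6, 12, 2, 116.16, 6, 4.88, ("caproic acid", "c6", "hexanoate", "n-hexanoic acid")),
    ("n-heptanoate", 7, 14, 2, 130.18, 7, 4.89, ("heptanoic acid", "c7", "enanthate")),
    ("n-caprylate", 8, 16, 2, 144.21, 8, 4.89, ("caprylic acid", "c8", "octanoate", "n-octanoic acid")),
]

_DEFAULT_ALIASES = {name: aliases for name, *_rest, aliases in _DEFAULTS}


def default_registry() -> SpeciesRegistry:
    """The packaged default registry: ethanol plus the C2–C8 carboxylates."""
    reg = SpeciesRegistry()
    for name, n_c, n_h, n_o, mm, cn, pka, aliases in _DEFAULTS:
        reg.register(
            CarboxylateSpecies(name, n_c, n_h, n_o, mm, cn, pka), aliases
        )
    return reg


def packaged_registry_csv():
    """Path-like handle to the packaged registry CSV (for config overrides)."""
    return importlib.resources.files("mccflux").joinpath("data/species.csv")


def to_cod(
    concentration: float,
    unit: str,
    species: str | CarboxylateSpecies,
    registry: Optional[SpeciesRegistry] = None,
) -> float:
    """Convert a concentration in g/L or mol/L to g COD/L.

    mol/L multiplies by the species COD factor; g/L first divides by the
    free-acid molar mass.
    """
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    if isinstance(species, str):
        species = (registry or default_registry()).get(species)
    if unit in ("mol/L", "mol_L", "M"):
        return concentration * species.cod_factor
    if unit in ("g/L", "g_L"):
        return concentration / species.molar_mass * species.cod_factor
    raise ValueError(f"unknown unit {unit!r}; expected g/L or mol/L")


def from_cod(
    concentration_gcod_l: float,
    species: str | CarboxylateSpecies,
    registry: Optional[SpeciesRegistry] = None,
) -> float:
    """Convert g COD/L to mmol/L using the species COD factor."""
    if concentration_gcod_l < 0:
        raise ValueError(f"negative concentration {concentration_gcod_l}")
    if isinstance(species, str):
        species = (registry or default_registry()).get(species)
    return concentration_gcod_l / species.cod_factor * 1000.0
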