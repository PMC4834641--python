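"""Material property tables and electron-backscatter physics.

The composition-sensitive contrast of energy-selective backscattered (EsB)
detectors is governed by the effective backscatter coefficient of the material
in the interaction volume.  This module provides

* an element table (atomic number, atomic mass, ionic radius),
* the empirical Heinrich polynomial ``eta(Z)`` for the atomic backscatter
  coefficient,
* the mass-fraction mixture rule ``eta_eff = sum_i eta_i c_i``,
* the harmonic density-mixing rule for electrolyte solutions and the
  resulting molarity ``1000 * rho_s * c_target / M_target``,
* a configurable calcium/phosphate electrolyte model (default Ca:P atomic
  ratio 1:2 with metaphosphate PO3 units, mirroring a calcium-polyphosphate
  storage phase).

All composition maps are *weight* (mass) fractions; there is deliberately no
mole-fraction API.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

AVOGADRO = 6.02214076e23
WATER_DENSITY = 0.9982  # g/cm^3 at 20 degC
WATER_MOLAR_MASS = 18.015

#: Cubic fit to Heinrich's backscatter data, eta(Z) = c0 + c1 Z + c2 Z^2 + c3 Z^3.
#: Swappable: pass alternative coefficients to :func:`heinrich_eta`.
HEINRICH_COEFFS = (-0.0254, 0.016, -1.86e-4, 8.3e-7)

#: The cubic extrapolates slightly negative at Z=1; floored here so that
#: eta stays in (0, 1) and strictly increasing over Z = 1..92.
ETA_FLOOR = 1e-4

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class MaterialError(ValueError):
    """Invalid material definition or unresolvable element symbol."""


@dataclass(frozen=True)
class ElementProps:
    symbol: str
    Z: int
    atomic_mass: float  # g/mol
    radius_pm: float | None = None  # ionic radius, used for ion densities
    ref_density: float | None = None  # g/cm^3

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise MaterialError(f"atomic number must be >= 1, got {self.Z}")
        if self.atomic_mass <= 0:
            raise MaterialError("atomic mass must be positive")
        if self.radius_pm is not None and self.radius_pm <= 0:
            raise MaterialError("radius must be positive when present")


def _load_elements() -> dict[str, ElementProps]:
    table = {}
    path = resources.files("coccoquant.data").joinpath("elements.csv")
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["symbol"]] = ElementProps(
                symbol=row["symbol"],
                Z=int(row["Z"]),
                atomic_mass=float(row["atomic_mass"]),
                radius_pm=float(row["radius_pm"]) if row["radius_pm"] else None,
                ref_density=float(row["ref_density"]) if row["ref_density"] else None,
            )
    return table


def _load_ion_radii() -> dict[str, float]:
    path = resources.files("coccoquant.data").joinpath("ion_radii.csv")
    with path.open() as fh:
        return {row["species"]: float(row["radius_pm"]) for row in csv.DictReader(fh)}


ELEMENTS: dict[str, ElementProps] = _load_elements()
ION_RADII_PM: dict[str, float] = _load_ion_radii()


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple chemical formula (no parentheses) into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise MaterialError(f"cannot parse formula {formula!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise MaterialError(f"unknown element {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise MaterialError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: str) -> float:
    """Molar mass (g/mol) of a formula unit."""
    return sum(ELEMENTS[s].atomic_mass * n for s, n in parse_formula(formula).items())


def formula_mass_fractions(formula: str) -> dict[str, float]:
    """Elemental weight fractions of a formula unit (e.g. CaCO3, CH2)."""
    counts = parse_formula(formula)
    total = formula_mass(formula)
    return {s: ELEMENTS[s].atomic_mass * n / total for s, n in counts.items()}


@dataclass
class Material:
    """A named material: elemental weight fractions plus optional density.

    ``density`` may be absent for solutions whose density is computed with the
    harmonic mixing rule (:func:`molarity_of_solution`).
    """

    name: str
    mass_fractions: dict[str, float]
    density: float | None = None  # g/cm^3

    def __post_init__(self) -> None:
        total = 0.0
        for sym, frac in self.mass_fractions.items():
            if sym not in ELEMENTS:
                raise MaterialError(f"unknown element symbol {sym!r} in {self.name!r}")
            if not 0.0 <= frac <= 1.0:
                raise MaterialError(f"mass fraction of {sym} out of [0,1]: {frac}")
            total += frac
        if abs(total - 1.0) > 1e-9:
            raise MaterialError(
                f"mass fractions of {self.name!r} sum to {total!r}, expected 1"
            )
        if self.density is not None and self.density <= 0:
            raise MaterialError("density must be positive")

    @classmethod
    def from_formula(cls, name: str, formula: str, density: float | None = None) -> "Material":
        return cls(name, formula_mass_fractions(formula), density)

    @classmethod
    def from_components(
        cls, name: str, components: Mapping[str, float], density: float | None = None
    ) -> "Material":
        """Build from species-level weight fractions (keys may be formulas).

        Fractions are renormalized to sum to exactly 1.
        """
        elemental: dict[str, float] = {}
        for formula, frac in components.items():
            if frac < 0:
                raise MaterialError(f"negative component fraction for {formula}")
            if frac == 0:
                continue
            for sym, f in formula_mass_fractions(formula).items():
                elemental[sym] = elemental.get(sym, 0.0) + frac * f
        total = sum(elemental.values())
        if total <= 0:
            raise MaterialError("empty composition")
        return cls(name, {s: f / total for s, f in elemental.items()}, density)


def load_material_yaml(path) -> Material:
    """Load a material from YAML (keys: name, density, and formula | fractions |
    components)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return material_from_dict(doc)


def material_from_dict(doc: Mapping) -> Material:
    name = doc.get("name", "unnamed")
    density = doc.get("density")
    if "formula" in doc:
        return Material.from_formula(name, doc["formula"], density)
    if "fractions" in doc:
        return Material(name, dict(doc["fractions"]), density)
    if "components" in doc:
        return Material.from_components(name, doc["components"], density)
    raise MaterialError(f"material {name!r} needs formula, fractions or components")


# ---------------------------------------------------------------------------
# Backscatter physics
# ---------------------------------------------------------------------------

def heinrich_eta(Z: int, coeffs: tuple[float, float, float, float] = HEINRICH_COEFFS) -> float:
    """Atomic backscatter coefficient from the empirical Heinrich cubic.

    Energy independence is assumed (adequate for light elements); the value
    is floored at ``ETA_FLOOR`` where the cubic extrapolates below zero
    (hydrogen only with the default coefficients).
    """
    if not 1 <= Z <= 92:
        raise ValueError(f"Z must be in 1..92, got {Z}")
    c0, c1, c2, c3 = coeffs
    eta = c0 + c1 * Z + c2 * Z**2 + c3 * Z**3
    return max(eta, ETA_FLOOR)


def eta_eff(material: Material) -> float:
    """Effective backscatter coefficient via the mixture rule
    ``eta_eff = sum_i eta_i * c_i`` over elemental weight fractions."""
    return sum(
        heinrich_eta(ELEMENTS[sym].Z) * frac
        for sym, frac in material.mass_fractions.items()
    )


# ---------------------------------------------------------------------------
# Solution density mixing and molarity
# ---------------------------------------------------------------------------

def ion_density(species: str, radius_pm: float | None = None) -> float:
    """Density (g/cm^3) of an ionic species modelled as a sphere of its
    tabulated radius: rho = (M / N_A) / (4/3 pi r^3)."""
    if radius_pm is None:
        try:
            radius_pm = ION_RADII_PM[species]
        except KeyError:
            raise MaterialError(f"no tabulated radius for species {species!r}") from None
    mass_g = formula_mass(species) / AVOGADRO
    r_cm = radius_pm * 1e-10
    return mass_g / (4.0 / 3.0 * math.pi * r_cm**3)


def solution_density(mass_fractions: Mapping[str, float], densities: Mapping[str, float]) -> float:
    """Harmonic density-mixing rule ``1/rho_s = sum_i c_i / rho_i``
    (water is just another species in the maps)."""
    total = sum(mass_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise MaterialError(f"species fractions sum to {total!r}, expected 1")
    inv = 0.0
    for sp, c in mass_fractions.items():
        if c == 0.0:
            continue
        rho = densities.get(sp)
        if rho is None or rho <= 0:
            raise MaterialError(f"missing or nonpositive density for species {sp!r}")
        inv += c / rho
    if inv <= 0:
        raise MaterialError("degenerate solution composition")
    return 1.0 / inv


def molarity_of_solution(
    solute_mass_fractions: Mapping[str, float],
    species_densities: Mapping[str, float],
    target_species: str,
    target_molar_mass: float | None = None,
) -> float:
    """Molar concentration (mol/L) of ``target_species`` in a solution.

    The solution density comes from the harmonic mixing rule; the molarity is
    ``1000 * rho_s * c_target / M_target`` with rho_s in g/cm^3.
    """
    rho_s = solution_density(solute_mass_fractions, species_densities)
    c = solute_mass_fractions.get(target_species, 0.0)
    if c == 0.0:
        return 0.0
    M = target_molar_mass if target_molar_mass is not None else formula_mass(target_species)
    return 1000.0 * rho_s * c / M


# ---------------------------------------------------------------------------
# Ca:P electrolyte model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrolyteModel:
    """Concentrated Ca/phosphate electrolyte with a fixed Ca:P atomic ratio.

    Default: ratio 1:2 with metaphosphate (PO3) chain units, i.e. a calcium-
    polyphosphate-like solution; no counterions added (charge imbalance is
    tolerated by the density model).
    """

    ca_p_atomic_ratio: tuple[float, float] = (1.0, 2.0)
    phosphate_unit: str = "PO3"
    counterion_policy: str = "none"
    water_density: float = WATER_DENSITY
    ion_radii_pm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ca_p_atomic_ratio[0] <= 0 or self.ca_p_atomic_ratio[1] <= 0:
            raise MaterialError("Ca:P ratio components must be positive")
        if "P" not in parse_formula(self.phosphate_unit):
            raise MaterialError("phosphate unit must contain P")

    @property
    def p_per_ca(self) -> float:
        return self.ca_p_atomic_ratio[1] / self.ca_p_atomic_ratio[0]

    @property
    def phosphate_mass_per_ca_mass(self) -> float:
        """Grams of phosphate units per gram of Ca ions at the fixed ratio."""
        n_p = parse_formula(self.phosphate_unit)["P"]
        units_per_ca = self.p_per_ca / n_p
        return units_per_ca * formula_mass(self.phosphate_unit) / ELEMENTS["Ca"].atomic_mass

    def max_ca_mass_fraction(self) -> float:
        """Largest Ca weight fraction with a consistent (water >= 0) composition."""
        return 1.0 / (1.0 + self.phosphate_mass_per_ca_mass)

    def species_fractions(self, ca_mass_fraction: float) -> dict[str, float]:
        """Species-level weight fractions {Ca, phosphate unit, H2O}."""
        if not 0.0 <= ca_mass_fraction < self.max_ca_mass_fraction() + 1e-12:
            raise MaterialError(
                f"ca_mass_fraction {ca_mass_fraction} outside "
                f"[0, {self.max_ca_mass_fraction():.6f}]"
            )
        w_p = ca_mass_fraction * self.phosphate_mass_per_ca_mass
        w_w = 1.0 - ca_mass_fraction - w_p
        return {"Ca": ca_mass_fraction, self.phosphate_unit: w_p, "H2O": max(w_w, 0.0)}

    def species_densities(self) -> dict[str, float]:
        return {
            "Ca": ion_density("Ca", self.ion_radii_pm.get("Ca")),
            self.phosphate_unit: ion_density(
                self.phosphate_unit, self.ion_radii_pm.get(self.phosphate_unit)
            ),
            "H2O": self.water_density,
        }


def build_electrolyte(ca_mass_fraction: float, model: ElectrolyteModel | None = None) -> Material:
    """Material (elemental weight fractions) of the electrolyte solution at a
    given Ca weight fraction; water fills the remainder."""
    model = model or ElectrolyteModel()
    species = model.species_fractions(ca_mass_fraction)
    name = f"electrolyte_CaP_{ca_mass_fraction:.6f}"
    return Material.from_components(name, species)


def electrolyte_molarity(ca_mass_fraction: float, model: ElectrolyteModel | None = None) -> float:
    """Ca molarity (mol/L) of the electrolyte at a Ca weight fraction, using
    ion densities derived from tabulated radii and harmonic density mixing."""
    model = model or ElectrolyteModel()
    return molarity_of_solution(
        model.species_fractions(ca_mass_fraction), model.species_densities(), "Ca"
    )


def ca_mass_fraction_for_molarity(
    molarity: float, model: ElectrolyteModel | None = None, tol: float = 1e-12
) -> float:
    """Invert :func:`electrolyte_molarity` (monotone) by bisection."""
    from scipy.optimize import brentq

    model = model or ElectrolyteModel()
    if molarity < 0:
        raise MaterialError("molarity must be >= 0")
    if molarity == 0.0:
        return 0.0
    w_max = model.max_ca_mass_fraction() - 1e-9
    m_max = electrolyte_molarity(w_max, model)
    if molarity > m_max:
        raise MaterialError(
            f"molarity {molarity} M exceeds the model's maximum {m_max:.2f} M"
        )
    return float(brentq(lambda w: electrolyte_molarity(w, model) - molarity, 0.0, w_max, xtol=tol))


# Commonly used materials ----------------------------------------------------

CALCITE_DENSITY = 2.71  # g/cm^3


def calcite() -> Material:
    return Material.from_formula("calcite", "CaCO3", density=CALCITE_DENSITY)


def lipid() -> Material:
    """Linear-hydrocarbon lipid body (largely CH2)."""
    return Material.from_formula("lipid_CH2", "CH2", density=0.90)


def water() -> Material:
    return Material.from_formula("water", "H2O", density=WATER_DENSITY)


def seawater_medium() -> Material:
    """Artificial seawater culture medium with 10 mM CaCl2 (shipped fixture)."""
    path = resources.files("coccoquant.data").joinpath("seawater_aquil.yaml")
    with path.open() as fh:
        return material_from_dict(yaml.safe_load(fh))


def calcite_ca_molarity() -> float:
    """Ca molarity of pure calcite: 1000 * 2.71 / 100.09 ~ 27.1 M."""
    return molarity_of_solution(
        {"CaCO3": 1.0}, {"CaCO3": CALCITE_DENSITY}, "CaCO3", formula_mass("CaCO3")
    )
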