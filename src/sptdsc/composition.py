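"""From solution recipe to hard-sphere packing state.

A solution is specified by its co-solutes (species + molarity) and its
*measured* density; the water content is never an input.  Water molarity is
recovered from the mass balance

    [H2O] = (rho - sum_j c_j * M_j) / M_water

after which every species (salts split into their ions) contributes a number
density rho_j = c_j * N_A / 1e27 (molecules per cubic Angstrom) and the
packing coefficients

    xi_i = (pi/6) * sum_j rho_j * sigma_j^i        i = 1, 2, 3

parameterize the scaled-particle-theory cavity work.  xi_3 is the volume
packing density: the fraction of space occupied by hard spheres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import MOLAR_TO_PER_A3, M_WATER
from .registry import Registry, Species, load_registry

__all__ = [
    "SolutionComposition",
    "PackingState",
    "InconsistentRecipeError",
    "UnphysicalPackingError",
    "water_molarity",
    "dissociate",
    "number_density",
    "packing_state",
]


class InconsistentRecipeError(ValueError):
    """Density is too low to accommodate the stated co-solute masses."""


class UnphysicalPackingError(ValueError):
    """Computed volume packing density reaches or exceeds 1."""


@dataclass(frozen=True)
class SolutionComposition:
    """A recipe: co-solutes at stated molarity plus the measured density.

    ``density`` is in g/L, molarities in mol/L, ``temperature`` in Celsius
    (recorded for provenance; densities in this study are at 25 C).
    """

    cosolutes: tuple[tuple[Species, float], ...]
    density: float
    temperature: float = 25.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if any(c < 0 for _, c in self.cosolutes):
            raise ValueError("molarities must be >= 0")


@dataclass(frozen=True)
class PackingState:
    """Number densities (molecules/A^3) and the xi packing coefficients."""

    species_densities: tuple[tuple[Species, float], ...]
    xi1: float = field(init=False)  # A^-2
    xi2: float = field(init=False)  # A^-1
    xi3: float = field(init=False)  # dimensionless

    def __post_init__(self) -> None:
        if any(rho < 0 for _, rho in self.species_densities):
            raise ValueError("number densities must be >= 0")
        for i, attr in ((1, "xi1"), (2, "xi2"), (3, "xi3")):
            val = (math.pi / 6.0) * sum(
                rho * sp.sigma**i for sp, rho in self.species_densities
            )
            object.__setattr__(self, attr, val)
        if self.xi3 >= 1.0:
            raise UnphysicalPackingError(
                f"volume packing density xi3 = {self.xi3:.3f} >= 1"
            )


def water_molarity(
    density: float, cosolutes: list[tuple[float, float]], label: str = ""
) -> float:
    """Water molarity from the solution mass balance.

    Parameters
    ----------
    density : float
        Measured solution density, g/L.
    cosolutes : list of (molar_mass g/mol, molarity mol/L)
        One entry per co-solute, salts *before* dissociation.

    Returns
    -------
    float
        mol/L of water such that water mass + co-solute masses = density.
    """
    solute_mass = sum(m * c for m, c in cosolutes)
    molarity = (density - solute_mass) / M_WATER
    if molarity <= 0:
        raise InconsistentRecipeError(
            f"solution {label or '<unnamed>'}: density {density} g/L cannot "
            f"accommodate {solute_mass:.1f} g/L of co-solutes"
        )
    return molarity


def dissociate(
    cosolutes: list[tuple[Species, float]], registry: Registry
) -> list[tuple[Species, float]]:
    """Replace each salt by its ions at stoichiometric molarity.

    Non-electrolytes pass through unchanged; the operation conserves mass
    and is idempotent (ions are not salts).
    """
    out: list[tuple[Species, float]] = []
    for sp, c in cosolutes:
        if sp.is_salt:
            for ion_name, count in sp.ions:
                out.append((registry[ion_name], c * count))
        else:
            out.append((sp, c))
    return out


def number_density(molarity: float) -> float:
    """mol/L -> molecules/A^3."""
    if molarity < 0:
        raise ValueError("molarity must be >= 0")
    return molarity * MOLAR_TO_PER_A3


def packing_state(
    comp: SolutionComposition,
    registry: Registry | None = None,
    water_override: float | None = None,
) -> PackingState:
    """Build the :class:`PackingState` for a solution recipe.

    Water is added automatically at the molarity implied by the measured
    density (or at ``water_override`` mol/L, to reproduce tabulations that
    used rounded water contents); salts are dissociated into their ions.
    """
    registry = registry or load_registry()
    if water_override is None:
        w = water_molarity(
            comp.density,
            [(sp.molar_mass, c) for sp, c in comp.cosolutes],
            label=comp.label,
        )
    else:
        w = water_override
    species = [(registry.water, w)] + dissociate(list(comp.cosolutes), registry)
    return PackingState(
        species_densities=tuple((sp, number_density(c)) for sp, c in species)
    )
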