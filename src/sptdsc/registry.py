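"""Species registry: molar masses, effective hard-sphere diameters, salt stoichiometry.

The default registry ships as ``data/species.tsv`` and covers water, the four
sugars (fructose, glucose, sucrose, trehalose), the molecular denaturants
(urea, tetramethylurea) and the three salts (NaClO4, GdmCl, GdmSCN) together
with their constituent ions.  Sugars are registered anhydrous.  Diameters are
the effective hard-sphere values used in excluded-volume work: van der Waals
volume increments for the sugars, equal-SASA spheres for urea/TMU/Gdm+,
Pauling-type radii for the halide-like anions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["Species", "Registry", "load_registry", "RegistryError"]


class RegistryError(KeyError):
    """Unknown species, or a species record violating its invariants."""


@dataclass(frozen=True)
class Species:
    """A solution component with hard-sphere parameters.

    Parameters
    ----------
    name : str
        Registry key.
    molar_mass : float
        g/mol; for a salt this must equal the summed ion masses.
    sigma : float or None
        Effective hard-sphere diameter in Angstrom. ``None`` for salts,
        which never enter packing sums directly (they dissociate first).
    ions : tuple of (str, int)
        Dissociation products as (ion name, stoichiometric count); empty
        for non-electrolytes.
    """

    name: str
    molar_mass: float
    sigma: float | None = None
    ions: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if not self.ions and (self.sigma is None or self.sigma <= 0):
            raise ValueError(f"{self.name}: non-salt species needs sigma > 0")
        if any(count < 1 for _, count in self.ions):
            raise ValueError(f"{self.name}: ion counts must be >= 1")

    @property
    def is_salt(self) -> bool:
        return bool(self.ions)


class Registry:
    """Lookup table of :class:`Species`, user-extensible."""

    def __init__(self, species: list[Species]):
        self._species = {s.name: s for s in species}
        self._validate_salts()

    def _validate_salts(self) -> None:
        for s in self._species.values():
            if not s.is_salt:
                continue
            ion_mass = 0.0
            for ion_name, count in s.ions:
                if ion_name not in self._species:
                    raise RegistryError(
                        f"salt {s.name!r} references unknown ion {ion_name!r}"
                    )
                ion_mass += count * self._species[ion_name].molar_mass
            if abs(ion_mass - s.molar_mass) > 0.01 * s.molar_mass:
                raise RegistryError(
                    f"salt {s.name!r}: ion masses sum to {ion_mass:.3f}, "
                    f"recorded molar mass is {s.molar_mass:.3f}"
                )

    def __getitem__(self, name: str) -> Species:
        try:
            return self._species[name]
        except KeyError:
            raise RegistryError(f"species {name!r} not in registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self._species

    def __iter__(self):
        return iter(self._species.values())

    def add(self, species: Species) -> None:
        self._species[species.name] = species
        self._validate_salts()

    @property
    def water(self) -> Species:
        return self["water"]


def _parse_ions(cell: str) -> tuple[tuple[str, int], ...]:
    if not cell or pd.isna(cell):
        return ()
    out = []
    for part in str(cell).split(";"):
        ion, _, count = part.partition(":")
        out.append((ion.strip(), int(count or 1)))
    return tuple(out)


def load_registry(path: str | Path | None = None) -> Registry:
    """Load a registry from a TSV file (default: the shipped table).

    Columns: ``name``, ``molar_mass_g_mol``, ``sigma_A`` (blank for salts),
    ``ions`` (semicolon-separated ``ion:count`` pairs, blank for non-salts).
    """
    if path is None:
        path = importlib.resources.files("sptdsc.data") / "species.tsv"
    df = pd.read_csv(path, sep="\t")
    species = []
    for row in df.itertuples(index=False):
        sigma = None if pd.isna(row.sigma_A) else float(row.sigma_A)
        species.append(
            Species(
                name=str(row.name),
                molar_mass=float(row.molar_mass_g_mol),
                sigma=sigma,
                ions=_parse_ions(getattr(row, "ions", "")),
            )
        )
    return Registry(species)
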