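"""Geometric two-macro-state protein model.

The native (N) state is a sphere and the denatured (D) state a prolate
spherocylinder chosen to have the *same* van der Waals volume (the volume
change on unfolding at 1 atm is negligible) but a much larger
solvent-accessible surface area.  Defaults describe a 138-residue model
globular protein: N-state a = 15 A; D-state a = 6 A, l = 117 A, which gives
V_vdW = 14,137 A^3 for both and SASA 3380 vs 6128 A^2 with a 1.4 A water
probe.  The conformational entropy gained on unfolding is taken as
19.0 J/K per residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CavityGeometry",
    "ProteinModel",
    "sasa",
    "vdw_volume",
    "conf_entropy_term",
    "NATIVE_GEOMETRY",
    "DENATURED_GEOMETRY",
    "DEFAULT_MODEL",
]


@dataclass(frozen=True)
class CavityGeometry:
    """A sphere (l = 0) or prolate spherocylinder (radius a, cylinder length l)."""

    a: float
    l: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("radius a must be > 0")
        if self.l < 0:
            raise ValueError("cylindrical length l must be >= 0")

    @property
    def shape(self) -> str:
        return "sphere" if self.l == 0 else "spherocylinder"

    @property
    def mean_radius(self) -> float:
        """Mean-curvature radius R_m = a + l/4 of the convex body."""
        return self.a + self.l / 4.0

    @property
    def surface_measure(self) -> float:
        """Area/(4 pi) = a^2 + a*l/2."""
        return self.a**2 + self.a * self.l / 2.0


def sasa(geom: CavityGeometry, probe: float = 1.4) -> float:
    """Solvent-accessible surface area: the parallel body at the probe radius.

    Sphere: 4 pi (a+p)^2; spherocylinder adds the lateral 2 pi (a+p) l.
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    r = geom.a + probe
    return 4.0 * math.pi * r**2 + 2.0 * math.pi * r * geom.l


def vdw_volume(geom: CavityGeometry) -> float:
    """van der Waals volume, A^3: (4/3) pi a^3 (+ pi a^2 l for the cylinder)."""
    return (4.0 / 3.0) * math.pi * geom.a**3 + math.pi * geom.a**2 * geom.l


def conf_entropy_term(n_res: int, T: float, ds_res: float = 19.0) -> float:
    """T * dS_conf in kJ/mol for ``n_res`` residues at ``T`` kelvin.

    ``ds_res`` is the per-residue conformational entropy gain on unfolding,
    J K^-1 per mol residue.
    """
    if n_res < 0:
        raise ValueError("n_res must be >= 0")
    if T <= 0:
        raise ValueError("T must be > 0 K")
    return T * ds_res * n_res / 1000.0


NATIVE_GEOMETRY = CavityGeometry(a=15.0)
DENATURED_GEOMETRY = CavityGeometry(a=6.0, l=117.0)


@dataclass(frozen=True)
class ProteinModel:
    """Bundle of the N/D geometries plus the chain-entropy parameters.

    The default is the 138-residue idealized globular protein; for RNase A
    itself use ``n_res=124`` (the model geometries are kept — they are an
    idealization, not a structure-derived shape).
    """

    n_res: int = 138
    n_state: CavityGeometry = NATIVE_GEOMETRY
    d_state: CavityGeometry = DENATURED_GEOMETRY
    probe_radius: float = 1.4
    ds_conf_res: float = 19.0

    def __post_init__(self) -> None:
        if self.n_res <= 0:
            raise ValueError("n_res must be > 0")
        v_n, v_d = vdw_volume(self.n_state), vdw_volume(self.d_state)
        if abs(v_n - v_d) > 1e-3 * v_n:
            raise ValueError(
                f"equal-volume constraint violated: V(N)={v_n:.0f}, V(D)={v_d:.0f} A^3"
            )
        if sasa(self.d_state, self.probe_radius) <= sasa(self.n_state, self.probe_radius):
            raise ValueError("D-state must expose more surface than the N-state")


DEFAULT_MODEL = ProteinModel()
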