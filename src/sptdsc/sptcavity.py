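"""Scaled-particle-theory work of cavity creation in a hard-sphere mixture.

Classic SPT gives the reversible work of creating a convex cavity — here a
sphere or prolate spherocylinder — in a mixture of hard spheres described by
packing coefficients xi_i = (pi/6) sum_j rho_j sigma_j^i:

    dG_c = RT * { -ln(1 - xi3)
                  + [6 xi2 / (1 - xi3)] * R_m
                  + [12 xi1 / (1 - xi3) + 18 xi2^2 / (1 - xi3)^2] * S_m }

with R_m = a + l/4 the mean-curvature radius and S_m = a^2 + a l / 2 the
surface measure (area / 4 pi) of the spherocylinder; l = 0 recovers the
spherical cavity.  The pressure-volume term of full SPT is omitted by
default: at 1 atm it is below 1 kJ/mol even for a 15 A cavity, far under
the precision of the hard-sphere diameters.

The stabilization of the compact native state by the solvent-excluded
volume effect is the difference ddG_c = dG_c(D) - dG_c(N) evaluated in the
same solution; its excess over the pure-water value (ddG_c') measures how
much a co-solute amplifies the effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

from .composition import PackingState
from .constants import N_AVOGADRO, P_STANDARD, R, T_REF
from .geometry import CavityGeometry

__all__ = ["CavityWork", "cavity_work", "ddGc", "ddGc_prime"]


@dataclass(frozen=True)
class CavityWork:
    """Cavity-creation work (kJ/mol) with its term-by-term breakdown."""

    total: float
    terms: dict[str, float]
    temperature: float

    def __post_init__(self) -> None:
        if abs(self.total - sum(self.terms.values())) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("total does not equal the sum of its terms")


def cavity_work(
    packing: PackingState,
    geom: CavityGeometry,
    T: float = T_REF,
    include_pv_term: bool = False,
) -> CavityWork:
    """Reversible work to create the cavity ``geom`` in ``packing`` at ``T`` K.

    Parameters
    ----------
    packing : PackingState
        Solution hard-sphere state; requires 0 <= xi3 < 1.
    geom : CavityGeometry
        Sphere (l = 0) or spherocylinder cavity.
    T : float
        Temperature in kelvin.
    include_pv_term : bool
        Add the P*V_cavity term of full SPT at 1 atm (negligible here;
        off by default to match the working equation).

    Returns
    -------
    CavityWork
        Total in kJ/mol plus the breakdown into the constant, curvature
        (linear in size) and surface (quadratic in size) contributions.
    """
    xi1, xi2, xi3 = packing.xi1, packing.xi2, packing.xi3
    if not 0.0 <= xi3 < 1.0:
        raise ValueError(f"xi3 = {xi3:.4f} outside [0, 1)")
    a, l = geom.a, geom.l
    q = 1.0 - xi3
    rt = R * T / 1000.0  # kJ/mol

    terms = {
        "log": rt * -log(q),
        "curvature_a": rt * (6.0 * xi2 / q) * a,
        "curvature_l": rt * (6.0 * xi2 / q) * (l / 4.0),
        "surface_a2": rt * (12.0 * xi1 / q + 18.0 * xi2**2 / q**2) * a**2,
        "surface_al": rt * (12.0 * xi1 / q + 18.0 * xi2**2 / q**2) * (a * l / 2.0),
    }
    if include_pv_term:
        from .geometry import vdw_volume

        # P*V per mole of cavities; V in A^3 -> m^3.
        terms["pressure_volume"] = (
            P_STANDARD * vdw_volume(geom) * 1e-30 * N_AVOGADRO / 1000.0
        )
    return CavityWork(total=sum(terms.values()), terms=terms, temperature=T)


def ddGc(
    packing: PackingState,
    n_geom: CavityGeometry,
    d_geom: CavityGeometry,
    T: float = T_REF,
) -> float:
    """D-state minus N-state cavity work in the same solution, kJ/mol."""
    return (
        cavity_work(packing, d_geom, T).total - cavity_work(packing, n_geom, T).total
    )


def ddGc_prime(ddgc_solution: float, ddgc_water: float) -> float:
    """Excess excluded-volume stabilization of a solution over pure water."""
    return ddgc_solution - ddgc_water
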