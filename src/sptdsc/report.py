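"""Assemble the study-level tables and the counteraction bookkeeping.

Three table builders reproduce the published layout: solution packing
(density, water molarity, xi coefficients), DSC thermodynamics (T_d,
dH_d, CU, Gibbs-Helmholtz dG_d at 25 C) and SPT cavity work (dG_c for the
N and D geometries, ddG_c and its excess over water).  On top of those sit
the stability decomposition

    dG_d = ddG_c - T dS_conf + dE_a

— solved for the residual attraction term dE_a, which is reported only as
a qualitative residual because the geometric model protein (138 residues)
is not RNase A (124 residues) — and the counteraction records pairing each
denaturant-only solution with its denaturant+sugar ternaries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .composition import SolutionComposition, packing_state, water_molarity
from .constants import T_CELSIUS_OFFSET, T_REF
from .dsc import gibbs_helmholtz
from .geometry import DEFAULT_MODEL, ProteinModel
from .registry import Registry, load_registry
from .sptcavity import cavity_work

__all__ = [
    "StabilityDecomposition",
    "CounteractionRecord",
    "load_solutions",
    "load_dsc_table",
    "decompose",
    "counteraction_table",
    "packing_table",
    "stability_table",
    "cavity_table",
]

#: Average denaturation heat-capacity change used for Gibbs-Helmholtz, kJ/K/mol.
DEFAULT_DCP = 6.4


@dataclass(frozen=True)
class StabilityDecomposition:
    """Bookkeeping of dG_d = ddG_c - T dS_conf + dE_a (all kJ/mol)."""

    dg_d: float
    ddgc: float
    ts_conf: float
    ea_residual: float
    n_res: int
    note: str = "qualitative - model-protein geometry vs RNase A"

    def __post_init__(self) -> None:
        if abs(self.ea_residual - (self.dg_d - self.ddgc + self.ts_conf)) > 1e-9:
            raise ValueError("decomposition identity violated")


@dataclass(frozen=True)
class CounteractionRecord:
    """Did a sugar restore thermal stability lost to a denaturant?"""

    denaturant: str
    sugar: str
    t_d_binary: float
    t_d_ternary: float
    delta_t_d: float
    ddgc_binary: float
    ddgc_ternary: float
    ddgc_prime_gain: float
    counteracted: bool

    def __post_init__(self) -> None:
        if abs(self.delta_t_d - (self.t_d_ternary - self.t_d_binary)) > 1e-9:
            raise ValueError("delta_t_d inconsistent")
        if self.counteracted != (self.delta_t_d > 0):
            raise ValueError("counteracted flag inconsistent with delta_t_d")


def _data_path(name: str):
    return importlib.resources.files("sptdsc.data") / name


def load_solutions(
    path: str | Path | None = None, registry: Registry | None = None
) -> list[SolutionComposition]:
    """Read the solution table (label, density_g_L, cosolutes ``name:M;...``)."""
    registry = registry or load_registry()
    df = pd.read_csv(path or _data_path("solutions.tsv"), sep="\t")
    out = []
    for row in df.itertuples(index=False):
        cell = getattr(row, "cosolutes", "")
        pairs = []
        if isinstance(cell, str) and cell.strip():
            for part in cell.split(";"):
                name, _, mol = part.partition(":")
                pairs.append((registry[name.strip()], float(mol)))
        out.append(
            SolutionComposition(
                cosolutes=tuple(pairs),
                density=float(row.density_g_L),
                label=str(row.label),
            )
        )
    return out


def load_dsc_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read the measured DSC summary (label, denaturant, sugar, td_C, dh_kJ_mol, ...)."""
    df = pd.read_csv(path or _data_path("rnase_dsc.tsv"), sep="\t")
    for col in ("denaturant", "sugar"):
        df[col] = df[col].fillna("")
    return df


def decompose(
    dg_d: float, ddgc: float, ts_conf: float, n_res: int = DEFAULT_MODEL.n_res
) -> StabilityDecomposition:
    """Solve the stability identity for the residual attraction term dE_a."""
    return StabilityDecomposition(
        dg_d=dg_d,
        ddgc=ddgc,
        ts_conf=ts_conf,
        ea_residual=dg_d - ddgc + ts_conf,
        n_res=n_res,
    )


def packing_table(
    solutions: list[SolutionComposition] | None = None,
    registry: Registry | None = None,
) -> pd.DataFrame:
    """Packing summary per solution: density, water molarity, sigmas, xi1-xi3."""
    registry = registry or load_registry()
    solutions = solutions if solutions is not None else load_solutions(registry=registry)
    rows = []
    for comp in solutions:
        state = packing_state(comp, registry)
        w = water_molarity(
            comp.density, [(sp.molar_mass, c) for sp, c in comp.cosolutes],
            label=comp.label,
        )
        sigmas = [sp.sigma for sp, _ in state.species_densities if sp.name != "water"]
        rows.append(
            {
                "label": comp.label,
                "density_g_L": comp.density,
                "water_M": round(w, 1),
                "sigma_A": ", ".join(f"{s:.2f}" for s in sigmas) or f"{registry.water.sigma:.2f}",
                "xi1": round(state.xi1, 4),
                "xi2": round(state.xi2, 4),
                "xi3": round(state.xi3, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "density_g_L", "water_M", "sigma_A", "xi1", "xi2", "xi3"],
    )


def stability_table(
    dsc: pd.DataFrame | None = None, dcp: float = DEFAULT_DCP
) -> pd.DataFrame:
    """DSC thermodynamics with the Gibbs-Helmholtz dG_d(25 C) recomputed.

    ``dG25_kJ_mol`` carries full precision; ``dG25_int`` the integer
    convention of the published table.
    """
    dsc = dsc if dsc is not None else load_dsc_table()
    out = dsc.copy()
    dg = [
        gibbs_helmholtz(td + T_CELSIUS_OFFSET, dh, dcp, T_REF)
        for td, dh in zip(out["td_C"], out["dh_kJ_mol"])
    ]
    out["dG25_kJ_mol"] = [round(float(x), 2) for x in dg]
    out["dG25_int"] = [int(round(float(x))) for x in dg]
    return out


def cavity_table(
    solutions: list[SolutionComposition] | None = None,
    registry: Registry | None = None,
    model: ProteinModel = DEFAULT_MODEL,
    T: float = T_REF,
    water_label: str = "water",
) -> pd.DataFrame:
    """Cavity-work table: dGc(N), dGc(D), ddGc and ddGc' per solution."""
    registry = registry or load_registry()
    solutions = solutions if solutions is not None else load_solutions(registry=registry)
    rows = []
    for comp in solutions:
        state = packing_state(comp, registry)
        gn = cavity_work(state, model.n_state, T).total
        gd = cavity_work(state, model.d_state, T).total
        rows.append(
            {"label": comp.label, "dGc_N": gn, "dGc_D": gd, "ddGc": gd - gn}
        )
    df = pd.DataFrame(rows, columns=["label", "dGc_N", "dGc_D", "ddGc"])
    ref = df.loc[df["label"] == water_label, "ddGc"]
    if len(ref) == 1:
        df["ddGc_prime"] = df["ddGc"] - float(ref.iloc[0])
    else:
        df["ddGc_prime"] = float("nan")
    for col in ("dGc_N", "dGc_D", "ddGc", "ddGc_prime"):
        df[col] = df[col].astype(float).round(1)
    return df


def counteraction_table(
    dsc: pd.DataFrame | None = None,
    cavity: pd.DataFrame | None = None,
) -> list[CounteractionRecord]:
    """One record per (denaturant, sugar) pair found in the DSC table.

    Binary reference = same denaturant with no sugar; the cavity table (as
    from :func:`cavity_table`) supplies ddGc by matching labels.  Counteraction
    is T_d(ternary) > T_d(binary); the measured T_d error is +/-0.2 C, so
    near-zero differences are at the resolution limit.
    """
    dsc = dsc if dsc is not None else load_dsc_table()
    cavity = cavity if cavity is not None else cavity_table()
    ddgc_by_label = dict(zip(cavity["label"], cavity["ddGc"]))
    binary = {
        row.denaturant: row
        for row in dsc.itertuples(index=False)
        if row.denaturant and not row.sugar
    }
    records = []
    for row in dsc.itertuples(index=False):
        if not (row.denaturant and row.sugar):
            continue
        if row.denaturant not in binary:
            raise KeyError(
                f"no denaturant-only reference for pair "
                f"({row.denaturant}, {row.sugar})"
            )
        ref = binary[row.denaturant]
        d_td = float(row.td_C) - float(ref.td_C)
        ddgc_bin = float(ddgc_by_label.get(ref.label, float("nan")))
        ddgc_ter = float(ddgc_by_label.get(row.label, float("nan")))
        records.append(
            CounteractionRecord(
                denaturant=row.denaturant,
                sugar=row.sugar,
                t_d_binary=float(ref.td_C),
                t_d_ternary=float(row.td_C),
                delta_t_d=d_td,
                ddgc_binary=ddgc_bin,
                ddgc_ternary=ddgc_ter,
                ddgc_prime_gain=ddgc_ter - ddgc_bin,
                counteracted=d_td > 0,
            )
        )
    return records
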