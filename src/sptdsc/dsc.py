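"""Two-state analysis of DSC thermograms and downstream thermodynamics.

Pipeline for a single scan: subtract the linear native-state baseline,
integrate the excess heat capacity to get the calorimetric enthalpy
dH_cal, fit the two-state excess heat capacity

    Cp_exc(T) = dH_vH^2 * K / (R T^2 (1 + K)^2),
    K(T)     = exp[-(dH_vH / R)(1/T - 1/T_d)]

for the van 't Hoff enthalpy dH_vH and midpoint T_d, and form the
cooperative unit CU = dH_cal / dH_vH (CU ~ 1 flags a genuine two-state
transition).  Across scans, the denaturation heat capacity change dC_p,d
is the slope of dH_d versus T_d, and the Gibbs-Helmholtz relation

    dG_d(T) = dH_d (1 - T/T_d) - dC_p,d [(T_d - T) + T ln(T/T_d)]

extrapolates the stability to a reference temperature (here 25 C).

Temperatures are handled in Celsius at the I/O boundary and kelvin inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import R, T_CELSIUS_OFFSET

__all__ = [
    "Thermogram",
    "TwoStateParams",
    "DenaturationResult",
    "CpRegression",
    "BaselineError",
    "FitError",
    "two_state_excess_cp",
    "fraction_denatured",
    "subtract_baseline",
    "calorimetric_enthalpy",
    "fit_two_state",
    "cooperative_unit",
    "cp_regression",
    "gibbs_helmholtz",
    "analyze_thermogram",
    "scan_area_difference",
]


class BaselineError(ValueError):
    """Native baseline window missing, out of range, or too small."""


class FitError(RuntimeError):
    """Two-state fit failed to converge; carries optimizer diagnostics."""


@dataclass(frozen=True)
class Thermogram:
    """A DSC scan: temperatures in Celsius, molar heat capacity in kJ/K/mol."""

    temperature: np.ndarray
    cp: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("temperature and cp must be equal-length 1-D arrays")
        if t.size < 20:
            raise ValueError("a thermogram needs at least 20 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "cp", c)

    @property
    def kelvin(self) -> np.ndarray:
        return self.temperature + T_CELSIUS_OFFSET

    @classmethod
    def read(cls, path, label: str = "") -> "Thermogram":
        """Read a two-column delimited file: temperature_C, cp_kJ_K_mol."""
        arr = np.loadtxt(path, ndmin=2)
        return cls(temperature=arr[:, 0], cp=arr[:, 1], label=label or str(path))

    def write(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.temperature, self.cp]),
            header="temperature_C\tcp_kJ_K_mol",
            delimiter="\t",
        )


@dataclass(frozen=True)
class TwoStateParams:
    """Midpoint (K) and van 't Hoff enthalpy (kJ/mol) of the two-state model."""

    t_d: float
    dh_vh: float
    baseline: tuple[float, float] = (0.0, 0.0)  # intercept, slope (vs Celsius)

    def __post_init__(self) -> None:
        if self.dh_vh <= 0:
            raise ValueError("dh_vh must be > 0")


@dataclass(frozen=True)
class DenaturationResult:
    """Per-scan summary mirroring a thermodynamic results table row."""

    label: str
    t_d: float  # Celsius
    dh_cal: float  # kJ/mol
    dh_vh: float  # kJ/mol
    cu: float
    dg_25: float | None = None  # kJ/mol
    two_state: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "two_state", 0.9 <= self.cu <= 1.1)


@dataclass(frozen=True)
class CpRegression:
    """OLS of dH_d on T_d; the slope is the denaturation dC_p,d."""

    slope: float  # kJ/K/mol
    intercept: float  # kJ/mol
    r: float
    stderr: float
    n: int


def two_state_excess_cp(
    T_kelvin: np.ndarray, t_d: float, dh_vh: float, kirchhoff_dcp: float = 0.0
) -> np.ndarray:
    """Excess heat capacity of a two-state transition, kJ/K/mol.

    ``t_d`` in kelvin, ``dh_vh`` in kJ/mol.  Evaluated in log-space for
    numerical safety far from the transition.  With ``kirchhoff_dcp``
    (kJ/K/mol) non-zero the van 't Hoff enthalpy acquires the Kirchhoff
    temperature dependence dH(T) = dH_vH + dcp (T - T_d) inside the
    equilibrium constant, and the sigmoidal dcp step under the peak is
    included; the default (0) is the plain two-state model, matching a
    workflow where dC_p,d is obtained afterwards from the dH_d-vs-T_d slope.
    """
    T = np.asarray(T_kelvin, dtype=float)
    dh_j = dh_vh * 1000.0
    if kirchhoff_dcp == 0.0:
        lnK = -(dh_j / R) * (1.0 / T - 1.0 / t_d)
        dh_T = dh_j
        step = 0.0
    else:
        dcp_j = kirchhoff_dcp * 1000.0
        dh_T = dh_j + dcp_j * (T - t_d)
        ds_T = dh_j / t_d + dcp_j * np.log(T / t_d)
        lnK = -(dh_T - T * ds_T) / (R * T)
        with np.errstate(over="ignore"):
            f_d = 1.0 / (1.0 + np.exp(-lnK))
        step = f_d * dcp_j
    # K/(1+K)^2 = 1/(4 cosh^2(lnK/2)); cosh overflow -> 0 contribution
    with np.errstate(over="ignore"):
        sech2 = 1.0 / np.cosh(lnK / 2.0) ** 2
    return (dh_T**2 * sech2 / (4.0 * R * T**2) + step) / 1000.0


def fraction_denatured(T_kelvin: np.ndarray, t_d: float, dh_vh: float) -> np.ndarray:
    """f_D = K/(1+K) of the two-state equilibrium (t_d in K, dh_vh in kJ/mol)."""
    T = np.asarray(T_kelvin, dtype=float)
    lnK = -(dh_vh * 1000.0 / R) * (1.0 / T - 1.0 / t_d)
    return 1.0 / (1.0 + np.exp(-lnK))


def subtract_baseline(
    raw: Thermogram,
    native_window: tuple[float, float],
    post_window: tuple[float, float] | None = None,
) -> tuple[Thermogram, tuple[float, float]]:
    """Fit the native linear baseline and subtract it over the whole scan.

    ``native_window`` is a (low, high) Celsius range lying before the
    transition; a straight line fitted there (least squares, >= 5 points)
    is extrapolated across the full temperature range.  Returns the excess
    heat-capacity thermogram and the (intercept, slope) of the baseline.

    By default only the native-side window is used.  Passing ``post_window``
    (a range after the transition) includes those points in the same linear
    fit, anchoring the far end of the extrapolation — advisable when the
    excess curve is integrated over a wide scan, where a small slope error
    in a one-sided baseline grows quadratically with scan width.
    """
    t = raw.temperature

    def window_mask(win, what):
        lo, hi = win
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
            raise BaselineError(
                f"{what} window ({lo}, {hi}) outside data range ({t[0]}, {t[-1]})"
            )
        return (t >= lo) & (t <= hi)

    mask = window_mask(native_window, "native")
    if mask.sum() < 5:
        raise BaselineError(
            f"native window contains {int(mask.sum())} points; need >= 5"
        )
    if post_window is not None:
        mask = mask | window_mask(post_window, "post-transition")
    res = stats.linregress(t[mask], raw.cp[mask])
    excess = raw.cp - (res.intercept + res.slope * t)
    return (
        Thermogram(temperature=t, cp=excess, label=raw.label),
        (float(res.intercept), float(res.slope)),
    )


def calorimetric_enthalpy(excess: Thermogram) -> float:
    """Trapezoidal integral of the excess heat capacity over T, kJ/mol."""
    cp = excess.cp
    peak = float(np.max(np.abs(cp))) if cp.size else 0.0
    if peak > 0 and (abs(cp[0]) > 0.05 * peak or abs(cp[-1]) > 0.05 * peak):
        warnings.warn(
            f"{excess.label or 'thermogram'}: excess heat capacity does not "
            "decay at the scan edges; the integral may be truncated",
            stacklevel=2,
        )
    return float(np.trapezoid(cp, excess.kelvin))


def fit_two_state(
    excess: Thermogram,
    init: TwoStateParams | None = None,
    max_nfev: int = 10000,
) -> tuple[TwoStateParams, dict]:
    """Least-squares fit of the two-state excess heat capacity.

    Initialization defaults to the peak position for T_d and the closed-form
    peak height Cp_max = dH_vH^2/(4 R T_d^2) for dH_vH.  dH_vH is bounded in
    (0, 2000] kJ/mol and T_d to the data range.  Returns the fitted
    parameters and diagnostics (residual norm, nfev).
    """
    T = excess.kelvin
    if init is None:
        i_max = int(np.argmax(excess.cp))
        t_d0 = float(T[i_max])
        cp_max = max(float(excess.cp[i_max]), 1e-6)
        dh0 = float(np.sqrt(4.0 * R * t_d0**2 * cp_max * 1000.0) / 1000.0)
        init = TwoStateParams(t_d=t_d0, dh_vh=min(dh0, 2000.0))

    def model(T, t_d, dh_vh):
        return two_state_excess_cp(T, t_d, dh_vh)

    try:
        popt, pcov, infodict, mesg, ier = optimize.curve_fit(
            model,
            T,
            excess.cp,
            p0=[init.t_d, init.dh_vh],
            bounds=([T[0], 1e-3], [T[-1], 2000.0]),
            max_nfev=max_nfev,
            full_output=True,
        )
    except RuntimeError as exc:
        raise FitError(f"two-state fit did not converge: {exc}") from exc
    residual = excess.cp - model(T, *popt)
    diagnostics = {
        "residual_norm": float(np.linalg.norm(residual)),
        "nfev": int(infodict.get("nfev", -1)),
        "message": mesg,
        "pcov": pcov,
    }
    return TwoStateParams(t_d=float(popt[0]), dh_vh=float(popt[1])), diagnostics


def cooperative_unit(dh_cal: float, dh_vh: float) -> float:
    """CU = dH_cal / dH_vH; values near 1 indicate a two-state transition."""
    if dh_vh <= 0:
        raise ValueError("dh_vh must be > 0")
    return dh_cal / dh_vh


def cp_regression(points: list[tuple[float, float]]) -> CpRegression:
    """OLS of denaturation enthalpy (kJ/mol) on midpoint temperature (K).

    The slope estimates dC_p,d.  Raises on a degenerate abscissa.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 (T_d, dH_d) points")
    t, h = np.asarray(points, dtype=float).T
    if np.ptp(t) == 0:
        raise ValueError("all T_d identical: regression is singular")
    res = stats.linregress(t, h)
    return CpRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        stderr=float(res.stderr),
        n=len(points),
    )


def gibbs_helmholtz(t_d: float, dh_d: float, dcp: float, T: float) -> float:
    """Gibbs energy of denaturation at ``T`` (kelvin), kJ/mol.

    ``t_d`` in kelvin, ``dh_d`` in kJ/mol at ``t_d``, ``dcp`` in kJ/K/mol
    assumed temperature-independent.  Zero at T = t_d by construction.
    """
    if t_d <= 0 or T <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    return dh_d * (1.0 - T / t_d) - dcp * ((t_d - T) + T * np.log(T / t_d))


def analyze_thermogram(
    raw: Thermogram,
    native_window: tuple[float, float],
    post_window: tuple[float, float] | None = None,
    dcp: float | None = None,
    t_ref: float = 25.0 + T_CELSIUS_OFFSET,
) -> DenaturationResult:
    """Full single-scan pipeline: baseline, integral, fit, CU (and dG if dcp given)."""
    excess, _ = subtract_baseline(raw, native_window, post_window)
    dh_cal = calorimetric_enthalpy(excess)
    params, _ = fit_two_state(excess)
    cu = cooperative_unit(dh_cal, params.dh_vh)
    dg = (
        float(gibbs_helmholtz(params.t_d, dh_cal, dcp, t_ref))
        if dcp is not None
        else None
    )
    return DenaturationResult(
        label=raw.label,
        t_d=params.t_d - T_CELSIUS_OFFSET,
        dh_cal=dh_cal,
        dh_vh=params.dh_vh,
        cu=cu,
        dg_25=dg,
    )


def scan_area_difference(first: Thermogram, second: Thermogram) -> float:
    """Relative area difference between two scans (reversibility plumbing)."""
    a1 = abs(calorimetric_enthalpy(first))
    a2 = abs(calorimetric_enthalpy(second))
    if a1 == 0:
        raise ValueError("first scan has zero area")
    return (a1 - a2) / a1
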