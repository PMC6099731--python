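"""Non-compartmental analysis of a dialysate concentration-time profile.

Cmax/Tmax are read directly from the observations, the terminal slope
(lambda_z) comes from an OLS fit of log concentration over the last points,
AUC0-t is the trapezoidal sum, AUC0-inf adds the Clast/lambda_z tail, and
the apparent oral parameters follow as CL/F = dose/AUC and
V/F = (CL/F)/lambda_z.  Units: dose mg/kg, concentration ng/mL, time h,
so CL/F comes out in L/h/kg and V/F in L/kg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ConcentrationTimeProfile

__all__ = [
    "ConcentrationTimeProfile",
    "TerminalPhase",
    "NCAResult",
    "auc_trapezoid",
    "terminal_slope",
    "nca_analyze",
    "apparent_clearance",
    "apparent_volume",
    "results_to_frame",
]

LN2 = float(np.log(2.0))

# dose mg/kg -> ng/kg is 1e6; AUC ng*h/mL gives mL/h/kg, -> L/h/kg is 1e-3;
# net factor 1e3 applied below.
_DOSE_FACTOR = 1e3


@dataclass(frozen=True)
class TerminalPhase:
    """Terminal log-linear phase: elimination rate and half-life."""

    lambda_z: float  # 1/h
    t_half: float  # h
    n_points: int
    intercept: float  # ln(concentration) at t = 0 extrapolated


@dataclass(frozen=True)
class NCAResult:
    """Model-free PK summary of one profile (apparent oral parameters)."""

    cmax: float  # ng/mL
    tmax: float  # h
    lambda_z: float  # 1/h
    t_half: float  # h
    auc_0_t: float  # ng*h/mL
    auc_0_inf: float  # ng*h/mL
    cl_f: float  # L/h/kg
    v_f: float  # L/kg
    dose: float | None = None  # mg/kg
    group: str = ""
    subject: str = ""


def auc_trapezoid(
    profile: ConcentrationTimeProfile | None = None,
    *,
    times: np.ndarray | None = None,
    concentrations: np.ndarray | None = None,
    method: str = "linear",
) -> float:
    """Area under the curve over the observed span (AUC0-t).

    ``method="linear"`` is the plain trapezoidal rule; ``"linlog"`` uses the
    log-trapezoid on strictly declining positive segments (linear-up,
    log-down), which is exact for mono-exponential decline.
    """
    if profile is not None:
        t, c = profile.times, profile.concentrations
    else:
        t = np.asarray(times, dtype=float)
        c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least two time points")
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method != "linlog":
        raise ValueError("method must be 'linear' or 'linlog'")
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    seg = 0.5 * dt * (c1 + c2)  # default linear
    down = (c2 < c1) & (c2 > 0) & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = dt * (c1 - c2) / np.log(c1 / c2)
    seg = np.where(down, log_seg, seg)
    return float(seg.sum())


def terminal_slope(
    profile: ConcentrationTimeProfile, n_terminal: int = 3
) -> TerminalPhase:
    """Estimate lambda_z by OLS of ln(concentration) over the last points.

    The last ``n_terminal`` concentrations must be strictly positive and,
    on balance, declining; a nonpositive fitted slope means no elimination
    phase is visible and is raised as an error.
    """
    if n_terminal < 2:
        raise ValueError("need at least 2 terminal points")
    if len(profile) < n_terminal:
        raise ValueError("profile shorter than the requested terminal window")
    t = profile.times[-n_terminal:]
    c = profile.concentrations[-n_terminal:]
    if np.any(c <= 0):
        raise ValueError("terminal window contains nonpositive concentrations")
    fit = stats.linregress(t, np.log(c))
    lam = -float(fit.slope)
    if lam <= 0:
        raise ValueError(
            "terminal concentrations do not decline; no elimination phase to fit"
        )
    return TerminalPhase(
        lambda_z=lam, t_half=LN2 / lam, n_points=n_terminal, intercept=float(fit.intercept)
    )


def apparent_clearance(dose_mg_kg: float, auc_ng_h_ml: float) -> float:
    """CL/F = dose/AUC with unit conversion: mg/kg over ng*h/mL -> L/h/kg."""
    if dose_mg_kg <= 0 or auc_ng_h_ml <= 0:
        raise ValueError("dose and AUC must be positive")
    return dose_mg_kg * _DOSE_FACTOR / auc_ng_h_ml


def apparent_volume(cl_f_l_h_kg: float, t_half_h: float) -> float:
    """V/F = (CL/F)/lambda_z = CL/F * t_half/ln2, in L/kg."""
    if cl_f_l_h_kg <= 0 or t_half_h <= 0:
        raise ValueError("clearance and half-life must be positive")
    return cl_f_l_h_kg * t_half_h / LN2


def nca_analyze(
    profile: ConcentrationTimeProfile,
    dose: float | None = None,
    n_terminal: int = 3,
    auc_basis: str = "0-t",
    vd_mode: str = "auc",
    auc_method: str = "linear",
) -> NCAResult:
    """Full non-compartmental summary of one profile.

    Parameters
    ----------
    dose
        Oral dose in mg/kg (defaults to ``profile.dose``).
    n_terminal
        Number of trailing observations for the lambda_z regression.
    auc_basis
        ``"0-t"`` (default) or ``"0-inf"``: which AUC enters CL/F = dose/AUC.
    vd_mode
        ``"auc"`` (default): V/F = (CL/F)/lambda_z, the convention that
        reproduces the reported dose-group values; ``"cmax"``: the literal
        V = dose/Cmax reading, kept as an alternative because the two differ
        by more than a factor of two on real profiles.
    auc_method
        Trapezoid flavor, ``"linear"`` or ``"linlog"``.

    Ties in Cmax break to the earliest time.
    """
    dose = profile.dose if dose is None else dose
    if dose is None or dose <= 0:
        raise ValueError("a positive dose (mg/kg) is required for CL/F and V/F")
    if auc_basis not in ("0-t", "0-inf"):
        raise ValueError("auc_basis must be '0-t' or '0-inf'")
    if vd_mode not in ("auc", "cmax"):
        raise ValueError("vd_mode must be 'auc' or 'cmax'")

    i_max = int(np.argmax(profile.concentrations))  # argmax takes first on ties
    cmax = float(profile.concentrations[i_max])
    tmax = float(profile.times[i_max])
    # lambda_z is fitted over the trailing positive observations, so a
    # terminal zero (below-LOQ) sample does not abort the analysis; it only
    # removes the extrapolation tail.
    pos = np.nonzero(profile.concentrations > 0)[0]
    if pos.size < n_terminal:
        raise ValueError("not enough positive observations for the terminal fit")
    last_pos = int(pos[-1])
    term_profile = ConcentrationTimeProfile(
        times=profile.times[: last_pos + 1],
        concentrations=profile.concentrations[: last_pos + 1],
        analyte=profile.analyte,
        dose=profile.dose,
        group=profile.group,
        subject=profile.subject,
    )
    term = terminal_slope(term_profile, n_terminal=n_terminal)
    auc_t = auc_trapezoid(profile, method=auc_method)
    c_last = float(profile.concentrations[-1])
    auc_inf = auc_t + (c_last / term.lambda_z if c_last > 0 else 0.0)

    auc_for_cl = auc_t if auc_basis == "0-t" else auc_inf
    cl_f = apparent_clearance(dose, auc_for_cl)  # L/h/kg
    if vd_mode == "auc":
        v_f = cl_f / term.lambda_z
    else:
        v_f = dose * _DOSE_FACTOR / cmax  # literal dose/Cmax reading
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        lambda_z=term.lambda_z,
        t_half=term.t_half,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        cl_f=cl_f,
        v_f=v_f,
        dose=dose,
        group=profile.group,
        subject=profile.subject,
    )


def results_to_frame(results: Iterable[NCAResult]) -> pd.DataFrame:
    """One row per subject, columns named after the usual PK report table."""
    results = list(results)
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "subject": [r.subject for r in results],
            "dose_mg_kg": [r.dose for r in results],
            "t_half_h": [r.t_half for r in results],
            "tmax_h": [r.tmax for r in results],
            "cmax_ng_ml": [r.cmax for r in results],
            "auc_0_t_ng_h_ml": [r.auc_0_t for r in results],
            "auc_0_inf_ng_h_ml": [r.auc_0_inf for r in results],
            "v_f_l_kg": [r.v_f for r in results],
            "cl_f_l_h_kg": [r.cl_f for r in results],
        }
    )
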