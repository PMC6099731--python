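"""Inhibitory indirect-response (turnover) model linking drug to biomarker.

The biomarker R (PGE2, pg/mL) is produced at a zero-order rate Kin and
eliminated first-order at Kout; the drug inhibits production through a
standard Imax = 1 inhibitory function of its concentration Cp:

    dR/dt = Kin * (1 - Cp/(Cp + IC50)) - Kout * R,

with pre-dose steady state R0 = Kin/Kout.  Because the drug acts on the
production rate rather than on R itself, the response nadir lags the
concentration peak (hysteresis), which is the observed ~1 h delay between
peak drug and maximal biomarker suppression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .pk import CompartmentParams, concentration_at
from .profiles import ConcentrationTimeProfile

__all__ = [
    "IndirectResponseParams",
    "PDFit",
    "PDFitError",
    "inhibition_factor",
    "simulate_response",
    "fit_pkpd",
]

_RTOL = 1e-8
_ATOL = 1e-10


@dataclass(frozen=True)
class IndirectResponseParams:
    """Turnover parameters: Kin (pg/mL/h), Kout (1/h), IC50 (ng/mL).

    ``r0`` defaults to the drug-free steady state Kin/Kout.
    """

    k_in: float
    k_out: float
    ic50: float
    r0: float | None = None

    def __post_init__(self) -> None:
        if self.k_in <= 0 or self.k_out <= 0:
            raise ValueError("k_in and k_out must be positive")
        if not (self.ic50 > 0 or np.isnan(self.ic50)):
            raise ValueError("ic50 must be positive (NaN only for flagged fits)")
        if self.r0 is not None and self.r0 <= 0:
            raise ValueError("r0 must be positive when given")

    @property
    def baseline(self) -> float:
        """Initial response: explicit r0 if set, else the steady state Kin/Kout."""
        return self.k_in / self.k_out if self.r0 is None else self.r0


def inhibition_factor(cp, ic50: float):
    """Fractional production remaining: 1 - Cp/(Cp + IC50) = IC50/(Cp + IC50).

    Equals 1 with no drug, 1/2 at Cp = IC50, and tends to 0 at high Cp
    (production fully suppressed, Imax = 1).
    """
    cp_arr = np.asarray(cp, dtype=float)
    if np.any(cp_arr < 0):
        raise ValueError("drug concentration must be nonnegative")
    if not ic50 > 0:
        raise ValueError("ic50 must be positive")
    out = ic50 / (cp_arr + ic50)
    return float(out) if cp_arr.ndim == 0 else out


def _as_cp_function(pk) -> Callable[[float], float]:
    if isinstance(pk, CompartmentParams):
        return lambda t: concentration_at(pk, t)
    if callable(pk):
        return pk
    raise TypeError("pk must be CompartmentParams or a callable t -> Cp")


def simulate_response(
    pd_params: IndirectResponseParams,
    pk,
    t_grid,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> np.ndarray:
    """Integrate the turnover ODE along ``t_grid`` (hours), returning R(t).

    ``pk`` is either fitted :class:`~micropkpd.pk.CompartmentParams` (the
    driving concentration is the oral one-compartment curve) or any callable
    ``t -> Cp`` (e.g. a constant-infusion lambda).  Integration starts at
    t = 0 from R(0) = baseline with an adaptive stiff-capable solver (LSODA)
    and the solution is interpolated to the requested grid.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be nonnegative and strictly increasing")
    cp_fn = _as_cp_function(pk)
    kin, kout, ic50 = pd_params.k_in, pd_params.k_out, pd_params.ic50

    def rhs(ti: float, y: np.ndarray) -> list[float]:
        return [kin * inhibition_factor(cp_fn(ti), ic50) - kout * y[0]]

    t_end = float(t[-1]) if t[-1] > 0 else 1e-9
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [pd_params.baseline],
        method="LSODA",
        t_eval=t,  # solver steps adaptively; requested times are interpolated
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"indirect-response ODE solver failed: {sol.message}")
    return sol.y[0]


class PDFitError(RuntimeError):
    """Optimizer failed to converge; ``best`` carries the last iterate."""

    def __init__(self, message: str, best: "PDFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class PDFit:
    """Fitted turnover parameters with diagnostics."""

    params: IndirectResponseParams
    residual_ss: float
    se: dict[str, float]
    n_obs: int
    success: bool
    message: str
    ic50_identifiable: bool = True


def fit_pkpd(
    effect_profile: ConcentrationTimeProfile,
    pk: CompartmentParams,
    init: IndirectResponseParams | None = None,
    tie_baseline: bool = True,
    weighting: str = "uniform",
) -> PDFit:
    """Sequential PD fit: PK fixed, (Kin, Kout, IC50) estimated by least squares.

    Requires >=5 observations whose first point is the pre-dose baseline
    (t = 0).  With ``tie_baseline`` (default) R(0) is constrained to
    Kin/Kout; otherwise R0 is a fourth free parameter.  If the observed
    response never drops meaningfully below baseline (no excursion), IC50 is
    unidentifiable: the fit is flagged (``ic50_identifiable=False``) and the
    returned IC50 is NaN rather than an arbitrary large number.

    Initialization exploits the quasi-steady state at the nadir,
    R_min/R0 ~ IC50/(Cp_nadir + IC50), to seed IC50 on the right scale.
    """
    t = effect_profile.times
    obs = effect_profile.concentrations
    if t.size < 5:
        raise ValueError("need >=5 effect observations")
    if t[0] != 0:
        raise ValueError("the first observation must be the pre-dose baseline at t=0")
    if weighting == "uniform":
        w = np.ones_like(obs)
    elif weighting == "1/y":
        w = 1.0 / np.sqrt(np.maximum(obs, 1e-12))
    else:
        raise ValueError("weighting must be 'uniform' or '1/y'")

    r0_obs = float(obs[0]) if obs[0] > 0 else float(np.max(obs))
    excursion = 1.0 - float(np.min(obs)) / r0_obs
    identifiable = excursion >= 0.05

    cp_obs = concentration_at(pk, t)
    if init is None:
        i_nadir = int(np.argmin(obs))
        frac = float(np.clip(obs[i_nadir] / r0_obs, 1e-6, 1 - 1e-6))
        cp_nadir = max(float(cp_obs[i_nadir]), 1e-9)
        ic50_0 = max(cp_nadir * frac / (1.0 - frac), 1e-6)
        kout_0 = 1.0
        init = IndirectResponseParams(
            k_in=r0_obs * kout_0, k_out=kout_0, ic50=ic50_0,
            r0=None if tie_baseline else r0_obs,
        )

    def build(theta: np.ndarray) -> IndirectResponseParams:
        vals = np.exp(theta)
        if tie_baseline:
            return IndirectResponseParams(k_in=vals[0], k_out=vals[1], ic50=vals[2])
        return IndirectResponseParams(
            k_in=vals[0], k_out=vals[1], ic50=vals[2], r0=vals[3]
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        sim = simulate_response(build(theta), pk, t)
        return (sim - obs) * w

    x0 = [np.log(init.k_in), np.log(init.k_out), np.log(init.ic50)]
    names = ["k_in", "k_out", "ic50"]
    if not tie_baseline:
        x0.append(np.log(init.r0 if init.r0 else init.k_in / init.k_out))
        names.append("r0")
    res = least_squares(
        residuals, np.asarray(x0), method="trf",
        ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=2000,
    )
    params = build(res.x)
    rss = float(2.0 * res.cost)
    dof = max(t.size - len(names), 1)
    try:
        cov_log = rss / dof * np.linalg.pinv(res.jac.T @ res.jac)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_log = np.full(len(names), np.nan)
    vals = np.exp(res.x)
    se = {name: float(v * s) for name, v, s in zip(names, vals, se_log)}

    # an IC50 pushed far beyond the observed Cp range is also unidentifiable
    if params.ic50 > 50.0 * max(float(np.max(cp_obs)), 1e-9):
        identifiable = False
    if not identifiable:
        warnings.warn(
            "no suppression excursion below baseline: IC50 is unidentifiable "
            "from this design; returning NaN",
            UserWarning,
            stacklevel=2,
        )
        params = IndirectResponseParams(
            k_in=params.k_in, k_out=params.k_out, ic50=float("nan"), r0=params.r0
        )
        se["ic50"] = float("nan")

    fit = PDFit(
        params=params,
        residual_ss=rss,
        se=se,
        n_obs=int(t.size),
        success=bool(res.success),
        message=str(res.message),
        ic50_identifiable=identifiable,
    )
    if not res.success:
        raise PDFitError(f"PD fit did not converge: {res.message}", best=fit)
    return fit
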