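"""One-compartment oral PK model (Bateman function) and its least-squares fit.

The model: first-order absorption at rate k01 into a single well-mixed
apparent volume V (really V/F after oral dosing), first-order elimination at
rate k10,

    C(t) = D*k01 / (V*(k01 - k10)) * (exp(-k10*t) - exp(-k01*t)),

with CL = V*k10.  The curve is symmetric under exchanging k01 and k10 with a
volume rescale (flip-flop kinetics), so a fit can only identify the pair; the
fitter reports a configured branch (default k01 > k10, absorption faster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .nca import terminal_slope
from .profiles import ConcentrationTimeProfile

__all__ = [
    "CompartmentParams",
    "PKFit",
    "PKFitError",
    "concentration_at",
    "tmax_cmax",
    "auc_analytic",
    "fit_pk",
]

MG_PER_KG_TO_NG = 1e6

# relative rate gap below which the equal-rate limit form is used
_DEGENERATE_RTOL = 1e-8


@dataclass(frozen=True)
class CompartmentParams:
    """Parameters of the one-compartment oral model.

    ``dose`` in ng/kg (use :meth:`from_mg_per_kg`), ``volume`` (V/F) in
    mL/kg so concentrations evaluate in ng/mL, rate constants in 1/h.
    """

    dose: float
    volume: float
    k01: float
    k10: float

    def __post_init__(self) -> None:
        if min(self.dose, self.volume, self.k01, self.k10) <= 0:
            raise ValueError("dose, volume, k01 and k10 must all be positive")

    @classmethod
    def from_mg_per_kg(
        cls, dose_mg_kg: float, volume_ml_kg: float, k01: float, k10: float
    ) -> "CompartmentParams":
        return cls(dose=dose_mg_kg * MG_PER_KG_TO_NG, volume=volume_ml_kg, k01=k01, k10=k10)

    @property
    def cl(self) -> float:
        """Apparent clearance CL/F = V*k10, mL/h/kg."""
        return self.volume * self.k10

    def flipped(self) -> "CompartmentParams":
        """The flip-flop twin with an identical curve.

        Exchanging the rates preserves the exponential pair; keeping the
        prefactor D*k01/V invariant requires rescaling the volume by
        k10/k01, so the twin is (k10, k01, V*k10/k01).
        """
        return CompartmentParams(
            dose=self.dose,
            volume=self.volume * self.k10 / self.k01,
            k01=self.k10,
            k10=self.k01,
        )


def concentration_at(params: CompartmentParams, t) -> np.ndarray | float:
    """Evaluate the Bateman curve at time(s) ``t`` (hours), in ng/mL.

    Near k01 == k10 the difference quotient degenerates; the analytic limit
    D*k*t*exp(-k*t)/V is used instead.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    d, v, ka, ke = params.dose, params.volume, params.k01, params.k10
    if abs(ka - ke) < _DEGENERATE_RTOL * ke:
        k = 0.5 * (ka + ke)
        out = d * k * t_arr * np.exp(-k * t_arr) / v
    else:
        out = d * ka / (v * (ka - ke)) * (np.exp(-ke * t_arr) - np.exp(-ka * t_arr))
    return float(out) if t_arr.ndim == 0 else out


def tmax_cmax(params: CompartmentParams) -> tuple[float, float]:
    """Closed-form peak: tmax = ln(k01/k10)/(k01 - k10), cmax = C(tmax).

    Degenerate equal rates give the limit tmax = 1/k.
    """
    ka, ke = params.k01, params.k10
    if abs(ka - ke) < _DEGENERATE_RTOL * ke:
        t_peak = 1.0 / (0.5 * (ka + ke))
    else:
        t_peak = float(np.log(ka / ke) / (ka - ke))
    return t_peak, concentration_at(params, t_peak)


def auc_analytic(params: CompartmentParams) -> float:
    """Total exposure integral over [0, inf): D/(V*k10), ng*h/mL (k01-free)."""
    return params.dose / (params.volume * params.k10)


class PKFitError(RuntimeError):
    """Optimizer failed to converge; ``best`` carries the last iterate."""

    def __init__(self, message: str, best: "PKFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class PKFit:
    """Fitted parameters with least-squares diagnostics."""

    params: CompartmentParams
    residual_ss: float
    se: dict[str, float]  # approximate SE of volume/k01/k10
    n_obs: int
    success: bool
    message: str

    def predict(self, t) -> np.ndarray | float:
        return concentration_at(self.params, t)


def _weights(conc: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "uniform":
        return np.ones_like(conc)
    if weighting == "1/y":
        return 1.0 / np.sqrt(np.maximum(conc, 1e-12))
    if weighting == "1/y2":
        return 1.0 / np.maximum(conc, 1e-12)
    raise ValueError("weighting must be 'uniform', '1/y' or '1/y2'")


def fit_pk(
    profile: ConcentrationTimeProfile,
    dose: float | None = None,
    init: CompartmentParams | None = None,
    weighting: str = "uniform",
    branch: str = "k01>k10",
) -> PKFit:
    """Least-squares fit of the Bateman model to one profile.

    The dose (mg/kg) is fixed; V, k01, k10 are estimated on the log scale so
    positivity holds by construction.  Needs >=4 time points with at least
    one observation after the empirical peak.  ``branch`` selects which
    flip-flop representative is returned: ``"k01>k10"`` (default) or
    ``"k10>k01"``.

    Default initial values: k10 from the terminal slope, k01 = 3*k10, and
    V = dose/(Cmax*e).
    """
    dose_mg = profile.dose if dose is None else dose
    if dose_mg is None or dose_mg <= 0:
        raise ValueError("a positive dose (mg/kg) is required")
    if branch not in ("k01>k10", "k10>k01"):
        raise ValueError("branch must be 'k01>k10' or 'k10>k01'")
    t = profile.times
    c = profile.concentrations
    if t.size < 4:
        raise ValueError("need >=4 time points to fit three parameters")
    if not np.any(c > 0):
        raise ValueError("all-zero profile cannot be fitted")
    i_peak = int(np.argmax(c))
    if i_peak == t.size - 1:
        raise ValueError("no post-peak observation; elimination is unconstrained")

    dose_ng = dose_mg * MG_PER_KG_TO_NG
    if init is None:
        try:
            lam = terminal_slope(profile).lambda_z
        except ValueError:
            lam = 0.5
        cmax = float(c.max())
        v0 = dose_ng / (cmax * np.e)
        init = CompartmentParams(dose=dose_ng, volume=v0, k01=3.0 * lam, k10=lam)

    w = _weights(c, weighting)

    def residuals(theta: np.ndarray) -> np.ndarray:
        v, ka, ke = np.exp(theta)
        p = CompartmentParams(dose=dose_ng, volume=v, k01=ka, k10=ke)
        return (concentration_at(p, t) - c) * w

    x0 = np.log([init.volume, init.k01, init.k10])
    res = least_squares(
        residuals, x0, method="trf", ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=2000
    )
    v, ka, ke = np.exp(res.x)
    params = CompartmentParams(dose=dose_ng, volume=v, k01=ka, k10=ke)
    want_fast_absorption = branch == "k01>k10"
    flipped = (params.k01 > params.k10) != want_fast_absorption and params.k01 != params.k10
    if flipped:
        params = params.flipped()

    rss = float(2.0 * res.cost)
    dof = max(t.size - 3, 1)
    try:
        cov_log = rss / dof * np.linalg.pinv(res.jac.T @ res.jac)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        se_log = np.full(3, np.nan)
    if flipped:  # relabel uncertainties to match the reported branch
        se_log = se_log[[0, 2, 1]]
    # delta method: SE on the natural scale ~ value * SE(log value)
    se = {
        "volume": float(params.volume * se_log[0]),
        "k01": float(params.k01 * se_log[1]),
        "k10": float(params.k10 * se_log[2]),
    }
    fit = PKFit(
        params=params,
        residual_ss=rss,
        se=se,
        n_obs=int(t.size),
        success=bool(res.success),
        message=str(res.message),
    )
    if not res.success:
        raise PKFitError(f"PK fit did not converge: {res.message}", best=fit)
    return fit
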