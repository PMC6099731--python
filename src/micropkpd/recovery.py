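"""Microdialysis probe recovery: relative recovery, relative loss, correction.

A microdialysis probe perfused at 0.5-2 uL/min never equilibrates with the
periprobe fluid, so the dialysate concentration is only a fraction of the
true extracellular concentration.  That fraction is estimated in vitro by
the incremental (gain) method, RR = Cdialysate/Cperfusate x 100%, and the
decremental (loss) method, RL = (Cperfusate - Cdialysate)/Cperfusate x 100%;
in vivo it is estimated by retrodialysis (drug in the perfusate, loss across
the membrane).  When gain and loss agree in vitro, the in vivo loss is a
valid surrogate for in vivo recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecoveryMeasurement",
    "RecoverySummary",
    "StabilityVerdict",
    "relative_recovery",
    "relative_loss",
    "recovery_percent",
    "summarize_recovery",
    "grand_mean",
    "correct_concentration",
    "stability_check",
    "read_recovery_table",
    "measurements_to_frame",
]

_METHODS = ("gain", "loss", "retrodialysis")


@dataclass(frozen=True)
class RecoveryMeasurement:
    """One probe calibration measurement.

    ``c_perfusate`` is the bath (periprobe) concentration for the gain
    method, and the inlet perfusate concentration for loss/retrodialysis;
    both in ug/mL.  ``flow_rate`` is the perfusion rate in uL/min.
    """

    c_perfusate: float
    c_dialysate: float
    flow_rate: float
    method: str
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.c_perfusate < 0 or self.c_dialysate < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.method in ("loss", "retrodialysis") and self.c_perfusate <= 0:
            raise ValueError(f"{self.method} requires a positive perfusate concentration")


@dataclass(frozen=True)
class RecoverySummary:
    """Per-condition mean +/- sample SD of recovery (or loss) percentages."""

    condition: str
    mean_rr: float
    sd_rr: float  # NaN for n == 1
    n: int


@dataclass(frozen=True)
class StabilityVerdict:
    """Coefficient of variation of a recovery time series and its pass flag."""

    mean: float
    cv: float  # fraction, SD/mean
    threshold: float
    passed: bool


def relative_recovery(m: RecoveryMeasurement) -> float:
    """Recovery by gain: 100 * Cdialysate / Cperfusate (percent).

    Requires a gain-mode measurement with a positive bath concentration.
    """
    if m.method != "gain":
        raise ValueError("relative_recovery applies to gain-mode measurements")
    if m.c_perfusate <= 0:
        raise ZeroDivisionError("gain method requires a positive periprobe concentration")
    rr = 100.0 * m.c_dialysate / m.c_perfusate
    if rr > 100.0:
        warnings.warn(
            f"relative recovery {rr:.2f}% exceeds 100% (measurement noise?)",
            UserWarning,
            stacklevel=2,
        )
    return rr


def relative_loss(m: RecoveryMeasurement) -> float:
    """Loss by reduction/retrodialysis: 100 * (Cperfusate - Cdialysate)/Cperfusate."""
    if m.method not in ("loss", "retrodialysis"):
        raise ValueError("relative_loss applies to loss or retrodialysis measurements")
    return 100.0 * (m.c_perfusate - m.c_dialysate) / m.c_perfusate


def recovery_percent(m: RecoveryMeasurement) -> float:
    """Method-appropriate percentage: RR for gain, RL otherwise."""
    return relative_recovery(m) if m.method == "gain" else relative_loss(m)


def summarize_recovery(
    measurements: Iterable[RecoveryMeasurement], by: str = "condition"
) -> list[RecoverySummary]:
    """Group measurements and report mean and sample SD of RR/RL per group.

    ``by`` may be ``"condition"``, ``"flow_rate"`` or ``"method"``.  The SD is
    the n-1 sample standard deviation; a single measurement yields NaN.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements to summarize")
    if by not in ("condition", "flow_rate", "method"):
        raise ValueError("by must be 'condition', 'flow_rate' or 'method'")
    groups: dict[str, list[float]] = {}
    for m in ms:
        key = str(getattr(m, by))
        groups.setdefault(key, []).append(recovery_percent(m))
    out = []
    for key in groups:
        vals = np.asarray(groups[key])
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan
        out.append(RecoverySummary(condition=key, mean_rr=float(vals.mean()), sd_rr=sd, n=vals.size))
    return out


def grand_mean(summaries: Sequence[RecoverySummary]) -> float:
    """Unweighted mean of per-condition means (the pooled probe figure)."""
    if not summaries:
        raise ValueError("no summaries")
    return float(np.mean([s.mean_rr for s in summaries]))


def correct_concentration(c_dialysate, recovery_fraction: float):
    """Convert a dialysate concentration to the periprobe concentration.

    Divides by the recovery fraction (in (0, 1]): a probe recovering 48% of
    the true concentration implies true = dialysate / 0.48.
    """
    if not 0.0 < recovery_fraction <= 1.0:
        raise ValueError("recovery_fraction must be in (0, 1]")
    return np.asarray(c_dialysate, dtype=float) / recovery_fraction if np.ndim(c_dialysate) else c_dialysate / recovery_fraction


def stability_check(
    hourly_rl: Sequence[float] | np.ndarray, threshold: float = 0.15
) -> StabilityVerdict:
    """Assess in vivo probe stability from an hourly loss series.

    Computes the coefficient of variation (sample SD over mean) across time
    points; the probe passes if CV <= ``threshold`` (default 15%, the assay
    precision bound).  Requires >=3 finite points; NaNs are rejected.
    """
    vals = np.asarray(hourly_rl, dtype=float)
    if vals.size == 0:
        raise ValueError("empty stability series")
    if np.any(~np.isfinite(vals)):
        raise ValueError("stability series contains NaN/inf values")
    if vals.size < 3:
        raise ValueError("need >=3 time points to assess stability")
    mean = float(vals.mean())
    if mean == 0:
        raise ValueError("mean recovery is zero; CV undefined")
    cv = float(np.std(vals, ddof=1) / mean)
    return StabilityVerdict(mean=mean, cv=cv, threshold=threshold, passed=cv <= threshold)


def read_recovery_table(path) -> list[RecoveryMeasurement]:
    """Read measurements from delimited text.

    Columns: ``method``, ``flow_rate_ul_min``, ``c_perfusate``,
    ``c_dialysate`` and optional ``condition_label``.
    """
    df = pd.read_csv(path, comment="#")
    required = {"method", "flow_rate_ul_min", "c_perfusate", "c_dialysate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"recovery file missing columns: {sorted(missing)}")
    has_cond = "condition_label" in df.columns
    return [
        RecoveryMeasurement(
            c_perfusate=row.c_perfusate,
            c_dialysate=row.c_dialysate,
            flow_rate=row.flow_rate_ul_min,
            method=row.method,
            condition=str(row.condition_label) if has_cond else None,
        )
        for row in df.itertuples()
    ]


def measurements_to_frame(measurements: Iterable[RecoveryMeasurement]) -> pd.DataFrame:
    """Tabulate measurements in the on-disk column layout."""
    measurements = list(measurements)
    return pd.DataFrame(
        {
            "method": [m.method for m in measurements],
            "flow_rate_ul_min": [m.flow_rate for m in measurements],
            "c_perfusate": [m.c_perfusate for m in measurements],
            "c_dialysate": [m.c_dialysate for m in measurements],
            "condition_label": [m.condition for m in measurements],
        }
    )
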