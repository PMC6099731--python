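"""Linear calibration of assay responses and back-calculation to concentrations.

Dialysate samples are quantified by tandem-MS against an internal standard:
the instrument reports the analyte/internal-standard peak-area ratio, which
is linear in concentration over the validated range (5-4000 ng/mL for the
drug, 100-10,000 pg/mL for the PGE2 biomarker).  This module fits that
calibration line by least squares and inverts it, carrying a range flag for
samples that fall outside the standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "CalibrationQualityWarning",
    "BackCalculated",
    "fit_calibration",
    "back_calculate",
    "read_standards",
    "fit_calibration_table",
]

#: Minimum Pearson correlation for a curve to count as assay-valid.
VALID_CORRELATION = 0.995


class CalibrationQualityWarning(UserWarning):
    """Calibration fit below the validated correlation threshold."""


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted line ``response = slope * concentration + intercept``.

    Parameters
    ----------
    analyte
        Label of the quantified species (e.g. ``"GE"`` or ``"PGE2"``).
    slope, intercept
        Regression coefficients in response-ratio units.
    correlation
        Pearson correlation of the calibration points.
    range_low, range_high
        Concentration span covered by the standards; back-calculated values
        outside it are flagged, not rejected.
    """

    analyte: str
    slope: float
    intercept: float
    correlation: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be below range_high")
        if not -1.0 <= self.correlation <= 1.0 + 1e-12:
            raise ValueError("correlation must lie in [-1, 1]")

    @property
    def is_valid(self) -> bool:
        """Whether the fit meets the assay-validation correlation bound."""
        return self.correlation >= VALID_CORRELATION

    def response_at(self, concentration):
        """Forward map: predicted response ratio at a concentration."""
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept


@dataclass(frozen=True)
class BackCalculated:
    """A back-calculated concentration with its calibration-range flag."""

    value: float | np.ndarray
    in_range: bool | np.ndarray


def fit_calibration(
    standards: Iterable[tuple[float, float]] | np.ndarray,
    analyte: str = "",
    weighting: str | None = None,
) -> CalibrationCurve:
    """Fit a straight calibration line through (concentration, response) pairs.

    Parameters
    ----------
    standards
        Iterable of ``(concentration, response_ratio)`` pairs; at least three
        distinct concentration levels are required.
    analyte
        Label stored on the returned curve.
    weighting
        ``None`` (unweighted, default), ``"1/x"`` or ``"1/x2"`` for variance
        proportional to concentration or its square.  The reported
        correlation is always the unweighted Pearson coefficient.

    Returns
    -------
    CalibrationCurve
        Fitted curve whose range is the span of the standards.  A curve with
        correlation below 0.995 is returned with a
        :class:`CalibrationQualityWarning`, not rejected.
    """
    arr = np.asarray(list(standards) if not isinstance(standards, np.ndarray) else standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (concentration, response) pairs")
    conc, resp = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 3:
        raise ValueError(
            "degenerate calibration design: need >=3 distinct concentration levels"
        )

    if weighting is None:
        w = np.ones_like(conc)
    elif weighting == "1/x":
        w = 1.0 / np.sqrt(conc)
    elif weighting == "1/x2":
        w = 1.0 / conc
    else:
        raise ValueError(f"unknown weighting {weighting!r}; use None, '1/x' or '1/x2'")
    if not np.all(np.isfinite(w)):
        raise ValueError("weighting 1/x requires strictly positive concentrations")

    slope, intercept = np.polyfit(conc, resp, 1, w=w)
    corr = float(stats.pearsonr(conc, resp).statistic)
    if corr < VALID_CORRELATION:
        warnings.warn(
            f"calibration for {analyte or 'analyte'}: correlation {corr:.5f} "
            f"below the validated bound {VALID_CORRELATION}",
            CalibrationQualityWarning,
            stacklevel=2,
        )
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        correlation=corr,
        range_low=float(conc.min()),
        range_high=float(conc.max()),
    )


def back_calculate(curve: CalibrationCurve, response) -> BackCalculated:
    """Invert the calibration line: concentration = (response - intercept)/slope.

    Values outside ``[range_low, range_high]`` are returned with
    ``in_range=False`` rather than raised: dialysate concentrations near a
    dosing peak can legitimately exceed the highest standard.
    """
    resp = np.asarray(response, dtype=float)
    value = (resp - curve.intercept) / curve.slope
    in_range = (value >= curve.range_low) & (value <= curve.range_high)
    if value.ndim == 0:
        return BackCalculated(value=float(value), in_range=bool(in_range))
    return BackCalculated(value=value, in_range=in_range)


def read_standards(path) -> pd.DataFrame:
    """Read calibration standards from delimited text.

    Expects columns ``analyte``, ``concentration``, ``response_ratio``.
    """
    df = pd.read_csv(path, comment="#")
    missing = {"analyte", "concentration", "response_ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"standards file missing columns: {sorted(missing)}")
    return df


def fit_calibration_table(
    standards: pd.DataFrame, weighting: str | None = None
) -> dict[str, CalibrationCurve]:
    """Fit one calibration curve per analyte in a standards table."""
    return {
        analyte: fit_calibration(
            grp[["concentration", "response_ratio"]].to_numpy(),
            analyte=analyte,
            weighting=weighting,
        )
        for analyte, grp in standards.groupby("analyte", sort=True)
    }
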