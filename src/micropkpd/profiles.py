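"""Concentration-time containers and their delimited-text round trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ConcentrationTimeProfile", "mean_profile", "read_profiles", "write_profiles"]


@dataclass
class ConcentrationTimeProfile:
    """One subject's (or a group mean's) analyte concentrations over time.

    Times are hours post-dose, strictly increasing and nonnegative;
    concentrations are ng/mL for the drug or pg/mL for the biomarker and
    must be nonnegative.  ``dose`` is the oral dose in mg/kg (None for
    undosed groups).
    """

    times: np.ndarray
    concentrations: np.ndarray
    analyte: str = ""
    dose: float | None = None
    group: str = ""
    subject: str = "mean"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")

    def __len__(self) -> int:
        return self.times.size


def mean_profile(profiles: Sequence[ConcentrationTimeProfile]) -> ConcentrationTimeProfile:
    """Pointwise mean of subject profiles sharing one sampling grid."""
    if not profiles:
        raise ValueError("no profiles to average")
    t0 = profiles[0].times
    for p in profiles[1:]:
        if not np.array_equal(p.times, t0):
            raise ValueError("profiles must share an identical time grid to average")
    conc = np.mean([p.concentrations for p in profiles], axis=0)
    first = profiles[0]
    return ConcentrationTimeProfile(
        times=t0.copy(),
        concentrations=conc,
        analyte=first.analyte,
        dose=first.dose,
        group=first.group,
        subject="mean",
    )


def write_profiles(
    profiles: Iterable[ConcentrationTimeProfile], path, header_comment: str | None = None
) -> None:
    """Write profiles as long-format CSV (group, subject, dose, analyte, time, conc)."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append(
                {
                    "group": p.group,
                    "subject": p.subject,
                    "dose_mg_kg": p.dose,
                    "analyte": p.analyte,
                    "time_h": t,
                    "concentration": c,
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_profiles(path) -> list[ConcentrationTimeProfile]:
    """Read long-format profile CSV back into per-subject containers."""
    df = pd.read_csv(path, comment="#")
    required = {"group", "subject", "analyte", "time_h", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile file missing columns: {sorted(missing)}")
    out = []
    for (group, subject, analyte), grp in df.groupby(
        ["group", "subject", "analyte"], sort=True, dropna=False
    ):
        grp = grp.sort_values("time_h")
        dose = grp["dose_mg_kg"].iloc[0] if "dose_mg_kg" in grp.columns else None
        out.append(
            ConcentrationTimeProfile(
                times=grp["time_h"].to_numpy(),
                concentrations=grp["concentration"].to_numpy(),
                analyte=str(analyte),
                dose=None if dose is None or pd.isna(dose) else float(dose),
                group=str(group),
                subject=str(subject),
            )
        )
    return out
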