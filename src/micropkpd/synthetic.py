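"""Synthetic microdialysis PK-PD studies with known ground truth.

Emulates the study design the analysis modules expect: five rat groups
(blank, untreated arthritic "model", and 30/60/120 mg/kg oral dose groups)
of n = 6, dialysate sampled hourly for 8 h post-dose, plus bench probe
calibration runs (gain and loss at four perfusion flow rates, n = 4 each)
and an 8 h in vivo retrodialysis stability series.

Default PK population values are calibrated so the dose-group mean curves
peak at Tmax = 2 h with the reported group-mean Cmax (124.5 / 469.3 / 805.9
ng/mL at 30 / 60 / 120 mg/kg): with k01 = 2*k10 the Bateman peak is
Cmax = D/(2V) at tmax = ln2/k10, so k10 = ln2/2 per hour and V follows from
each dose's Cmax.  Default PD population values are the reported per-dose
turnover estimates (Kin, Kout, IC50).  Between-subject variability is
log-normal (median at the population value) and assay noise is proportional
(Gaussian CV), both defaulting to the levels the recovery benchmarks use
(20% and 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pk import CompartmentParams, concentration_at, MG_PER_KG_TO_NG
from .pkpd import IndirectResponseParams, simulate_response
from .profiles import ConcentrationTimeProfile
from .recovery import RecoveryMeasurement

__all__ = [
    "GroupSpec",
    "StudyDesign",
    "TruthRecord",
    "default_pk_population",
    "default_pd_population",
    "generate_pk_profiles",
    "generate_pd_profiles",
    "generate_recovery_experiment",
    "generate_stability_series",
]

#: Quantification limits of the validated assays (flagging only, no censoring).
LOQ_DRUG_NG_ML = 5.0
LOQ_BIOMARKER_PG_ML = 100.0

#: Dose-group mean peak concentrations (ng/mL) the PK defaults are calibrated to.
_CMAX_TARGET = {30.0: 124.479, 60.0: 469.258, 120.0: 805.906}

#: Absorption/elimination rates giving Tmax = 2 h exactly (k01 = 2*k10).
_K10_DEFAULT = float(np.log(2.0) / 2.0)  # 0.3466 /h
_K01_DEFAULT = 2.0 * _K10_DEFAULT

#: Reported per-dose turnover estimates (Kin pg/mL/h, Kout 1/h, IC50 ng/mL).
_PD_TABLE = {
    30.0: (523.75, 0.97, 0.74),
    60.0: (556.5, 1.08, 2.62),
    120.0: (272.78, 0.53, 1.81),
}

#: Bench transfer fractions by perfusion flow rate (uL/min), declining in flow.
DEFAULT_TRANSFER_BY_FLOW = {0.5: 0.5645, 0.8: 0.5287, 1.0: 0.4805, 2.0: 0.2563}

#: Bench transfer fractions by bath concentration (ug/mL), flat in concentration.
DEFAULT_TRANSFER_BY_CONCENTRATION = {50.0: 0.2709, 100.0: 0.2898, 200.0: 0.2807}


@dataclass(frozen=True)
class GroupSpec:
    """One study arm: label, oral dose in mg/kg (0 for undosed), group size."""

    label: str
    dose: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >=1")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")


@dataclass(frozen=True)
class StudyDesign:
    """Study layout: arms, hourly 0-8 h sampling grid, and the master seed."""

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("blank", 0.0, 6),
        GroupSpec("model", 0.0, 6),
        GroupSpec("low", 30.0, 6),
        GroupSpec("medium", 60.0, 6),
        GroupSpec("high", 120.0, 6),
    )
    times: tuple[float, ...] = tuple(float(h) for h in range(9))
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be increasing")

    @property
    def dosed_groups(self) -> tuple[GroupSpec, ...]:
        return tuple(g for g in self.groups if g.dose > 0)


@dataclass
class TruthRecord:
    """Per-subject true parameters and the noise model, for recovery scoring."""

    seed: int
    noise_cv: float
    iiv_cv: float
    pk: dict[tuple[str, str], CompartmentParams] = field(default_factory=dict)
    pd: dict[tuple[str, str], IndirectResponseParams] = field(default_factory=dict)
    n_truncated: int = 0


def default_pk_population(dose: float) -> CompartmentParams:
    """Population Bateman parameters for one dose group (mg/kg).

    Rates are dose-independent (k01 = 2*k10 = ln2 per hour); the apparent
    volume is set per dose from the calibrated mean Cmax = D/(2V).
    """
    if dose not in _CMAX_TARGET:
        raise ValueError(f"no default population for dose {dose} mg/kg")
    dose_ng = dose * MG_PER_KG_TO_NG
    volume = dose_ng / (2.0 * _CMAX_TARGET[dose])  # mL/kg
    return CompartmentParams(dose=dose_ng, volume=volume, k01=_K01_DEFAULT, k10=_K10_DEFAULT)


def default_pd_population(dose: float) -> IndirectResponseParams:
    """Population turnover parameters for one dose group (mg/kg)."""
    if dose not in _PD_TABLE:
        raise ValueError(f"no default PD population for dose {dose} mg/kg")
    kin, kout, ic50 = _PD_TABLE[dose]
    return IndirectResponseParams(k_in=kin, k_out=kout, ic50=ic50)


def _lognormal_draw(rng: np.random.Generator, median: float, cv: float) -> float:
    if cv <= 0:
        return median
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _apply_noise(
    rng: np.random.Generator, values: np.ndarray, noise_cv: float
) -> tuple[np.ndarray, int]:
    if noise_cv <= 0:
        return values.copy(), 0
    noisy = values * (1.0 + rng.normal(0.0, noise_cv, size=values.shape))
    n_trunc = int(np.sum(noisy < 0))
    return np.maximum(noisy, 0.0), n_trunc


def generate_pk_profiles(
    design: StudyDesign | None = None,
    population: Mapping[float, CompartmentParams] | None = None,
    iiv_cv: float = 0.2,
    noise_cv: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[list[ConcentrationTimeProfile], TruthRecord]:
    """Simulate per-subject drug concentration-time profiles for dosed groups.

    Subject parameters (V, k01, k10) are drawn log-normally around the
    population values with coefficient of variation ``iiv_cv``; observations
    are the subject's Bateman curve times ``1 + N(0, noise_cv)``, truncated
    at zero (truncations counted on the truth record).
    """
    design = design or StudyDesign()
    if not 0 <= iiv_cv < 2 or not 0 <= noise_cv < 2:
        raise ValueError("CVs must be fractions in [0, 2)")
    rng = np.random.default_rng(design.seed) if rng is None else rng
    times = np.asarray(design.times)
    truth = TruthRecord(seed=design.seed, noise_cv=noise_cv, iiv_cv=iiv_cv)
    profiles = []
    for g in design.dosed_groups:
        pop = (population or {}).get(g.dose) or default_pk_population(g.dose)
        for i in range(1, g.n + 1):
            subject = f"{g.label}-{i:02d}"
            p = CompartmentParams(
                dose=pop.dose,
                volume=_lognormal_draw(rng, pop.volume, iiv_cv),
                k01=_lognormal_draw(rng, pop.k01, iiv_cv),
                k10=_lognormal_draw(rng, pop.k10, iiv_cv),
            )
            truth.pk[(g.label, subject)] = p
            clean = concentration_at(p, times)
            obs, n_trunc = _apply_noise(rng, clean, noise_cv)
            truth.n_truncated += n_trunc
            profiles.append(
                ConcentrationTimeProfile(
                    times=times.copy(),
                    concentrations=obs,
                    analyte="GE",
                    dose=g.dose,
                    group=g.label,
                    subject=subject,
                    meta={
                        "seed": design.seed,
                        "n_below_loq": int(np.sum(obs < LOQ_DRUG_NG_ML)),
                    },
                )
            )
    return profiles, truth


def generate_pd_profiles(
    design: StudyDesign | None = None,
    pd_population: Mapping[float, IndirectResponseParams] | None = None,
    pk_truth: TruthRecord | None = None,
    iiv_cv: float = 0.2,
    noise_cv: float = 0.1,
    blank_baseline: float = 150.0,
    model_baseline: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ConcentrationTimeProfile], TruthRecord]:
    """Simulate biomarker (PGE2) profiles for every study arm.

    Dosed subjects integrate the turnover ODE driven by their own true PK
    curve from ``pk_truth`` (missing subjects are an error).  The untreated
    "model" arm holds its elevated stationary baseline (default: the
    medium-dose Kin/Kout steady state) and the blank arm a lower healthy
    baseline; both are flat apart from noise and subject-level variability.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(design.seed + 1) if rng is None else rng
    times = np.asarray(design.times)
    truth = TruthRecord(seed=design.seed, noise_cv=noise_cv, iiv_cv=iiv_cv)
    if model_baseline is None:
        kin, kout, _ = _PD_TABLE[60.0]
        model_baseline = kin / kout  # elevated arthritic steady state
    profiles = []
    for g in design.groups:
        if g.dose > 0:
            if pk_truth is None:
                raise ValueError("pk_truth is required for dosed groups")
            pop = (pd_population or {}).get(g.dose) or default_pd_population(g.dose)
        for i in range(1, g.n + 1):
            subject = f"{g.label}-{i:02d}"
            if g.dose > 0:
                key = (g.label, subject)
                if key not in pk_truth.pk:
                    raise ValueError(f"pk_truth missing subject {key}")
                pd_i = IndirectResponseParams(
                    k_in=_lognormal_draw(rng, pop.k_in, iiv_cv),
                    k_out=_lognormal_draw(rng, pop.k_out, iiv_cv),
                    ic50=_lognormal_draw(rng, pop.ic50, iiv_cv),
                )
                clean = simulate_response(pd_i, pk_truth.pk[key], times)
            else:
                base = blank_baseline if g.label == "blank" else model_baseline
                base_i = _lognormal_draw(rng, base, iiv_cv)
                # drug-free stationary turnover: R(t) = Kin/Kout = baseline
                pd_i = IndirectResponseParams(k_in=base_i, k_out=1.0, ic50=1.0)
                clean = np.full_like(times, base_i, dtype=float)
            truth.pd[(g.label, subject)] = pd_i
            obs, n_trunc = _apply_noise(rng, clean, noise_cv)
            truth.n_truncated += n_trunc
            profiles.append(
                ConcentrationTimeProfile(
                    times=times.copy(),
                    concentrations=obs,
                    analyte="PGE2",
                    dose=g.dose if g.dose > 0 else None,
                    group=g.label,
                    subject=subject,
                    meta={
                        "seed": design.seed,
                        "n_below_loq": int(np.sum(obs < LOQ_BIOMARKER_PG_ML)),
                    },
                )
            )
    return profiles, truth


def generate_recovery_experiment(
    transfer_fraction_by_flow: Mapping[float, float] | None = None,
    bath_concentration: float = 100.0,
    noise_cv: float = 0.08,
    n_per_condition: int = 4,
    methods: Sequence[str] = ("gain", "loss"),
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[RecoveryMeasurement]:
    """Simulate a bench probe calibration across flow rates (or conditions).

    The probe is modeled by a single membrane transfer fraction f per
    condition, symmetric between directions: gain-mode dialysate is
    f x bath, loss-mode dialysate is (1 - f) x perfusate, each times a
    proportional noise term.  Defaults reproduce the observed decline of
    recovery with perfusion flow (f = 0.56 -> 0.26 over 0.5 -> 2 uL/min,
    n = 4 samples per condition).
    """
    fractions = dict(transfer_fraction_by_flow or DEFAULT_TRANSFER_BY_FLOW)
    for f in fractions.values():
        if not 0.0 < f < 1.0:
            raise ValueError("transfer fractions must lie in (0, 1)")
    if bath_concentration <= 0:
        raise ValueError("bath_concentration must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    out = []
    for flow in sorted(fractions):
        f = fractions[flow]
        for method in methods:
            for _ in range(n_per_condition):
                eps = 1.0 + (rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0)
                if method == "gain":
                    c_dial = max(f * bath_concentration * eps, 0.0)
                else:
                    c_dial = max((1.0 - f) * bath_concentration * eps, 0.0)
                out.append(
                    RecoveryMeasurement(
                        c_perfusate=bath_concentration,
                        c_dialysate=c_dial,
                        flow_rate=flow,
                        method=method,
                        condition=f"{flow:g} uL/min",
                    )
                )
    return out


def generate_stability_series(
    transfer_fraction: float = 0.2907,
    hours: int = 8,
    noise_cv: float = 0.03,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Hourly in vivo retrodialysis loss series (%) over an 8 h session.

    A stable probe keeps a constant transfer fraction; only assay noise
    perturbs the hourly relative-loss values.
    """
    if not 0.0 < transfer_fraction < 1.0:
        raise ValueError("transfer_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    eps = 1.0 + rng.normal(0.0, noise_cv, size=hours)
    return 100.0 * transfer_fraction * eps
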