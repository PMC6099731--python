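# Methods

## Scope and model chain

The package covers the quantitative chain of a microdialysis PK–PD study in
arthritic rats: assay calibration, probe recovery, non-compartmental
analysis (NCA), a one-compartment oral PK model, and an inhibitory
indirect-response PD model. Dialysate concentrations are treated as
measured free concentrations at the sampling site; all "apparent" oral
parameters (V/F, CL/F) are confounded with bioavailability F, and no
separate lag-time or F parameter is estimated.

## Calibration (`quantify`)

Responses are analyte/internal-standard peak-area ratios, linear in
concentration. The fit is ordinary least squares; no weighting is applied
by default because the validated assays quote near-perfect linearity over
their ranges (5–4000 ng/mL drug, 100–10,000 pg/mL biomarker), but `1/x` and
`1/x²` weights are available for heteroscedastic standards. A Pearson
correlation below 0.995 marks the curve as failing assay validation — a
warning, not an error. Back-calculated values outside the standards carry
an out-of-range flag rather than raising: dialysate peaks can legitimately
exceed the top standard. Replicate averaging is left to the caller; the
module quantifies whatever responses it is given.

## Probe recovery (`recovery`)

A perfused probe never equilibrates, so the dialysate holds only a fraction
of the periprobe concentration. Recovery by gain (probe in a bath, blank
perfusate) and loss by reduction (drug in the perfusate, blank bath) are

    RR = C_dial/C_perf × 100%,    RL = (C_perf − C_dial)/C_perf × 100%.

When the membrane transfer fraction is direction-symmetric these coincide,
which is what licenses in vivo retrodialysis (loss measured in situ) as the
in vivo recovery estimate. Summaries report the n−1 sample SD; recoveries
above 100% are admitted with a warning (assay noise), never clipped.
Stability over a session is judged by the CV of the hourly loss series,
with a 15% default threshold matching the assay-precision bound.

Correction of concentration profiles (division by the recovery fraction) is
implemented but **off by default** in the pipeline: dose-group NCA tables
from such studies are internally consistent on the uncorrected dialysate
scale (D/AUC reproduces the tabulated CL/F), so correction is an explicit
opt-in flag rather than silent behavior.

## NCA (`nca`)

Cmax/Tmax are read from the observations (ties break to the earliest
time). λz is the negative OLS slope of ln C over the last three positive
observations by default (window configurable); a non-declining terminal
phase is an error, since extrapolation would be meaningless. AUC₀₋ₜ uses
the plain linear trapezoid; a linear-up/log-down flavor is available.
AUC₀₋∞ adds C_last/λz, omitted when the last sample is zero (below-LOQ
tail). Units are chosen so mg/kg doses over ng·h/mL AUCs give CL/F in
L/h/kg directly.

Two volume conventions circulate for oral NCA. The rule V = D/Cmax ignores
elimination during absorption and overstates V/F by more than a factor of
two on profiles like these; the default here is therefore
V/F = (CL/F)/λz, which is the convention consistent with the published
dose-group tables this package is benchmarked against. The literal D/Cmax
reading is retained as `vd_mode="cmax"` because reports sometimes quote it.
CL/F defaults to the AUC₀₋ₜ basis (configurable to AUC₀₋∞), again matching
the benchmark tables slightly better.

## One-compartment oral PK (`pk`)

The Bateman function is evaluated in closed form; within a relative rate
gap of 1e−8 the equal-rate limit D·k·t·e^(−kt)/V is used, keeping the
surface continuous. Peak time ln(k01/k10)/(k01 − k10) and AUC D/(V·k10)
are closed-form.

The curve is invariant under exchanging the rates with a volume rescale:
(k01, k10, V) and (k10, k01, V·k10/k01) are pointwise identical (the
rescale keeps the prefactor D·k01/V unchanged). A fit therefore identifies
only the rate pair; `fit_pk` canonicalizes to a configured branch (default
k01 > k10, absorption faster) and the twin is one method call away. This
matters here: the observed 2 h peak and sub-hour tabulated half-life cannot
both hold in one Bateman curve, so which rate the terminal slope reflects
is genuinely ambiguous, and the package surfaces both branches instead of
resolving the ambiguity.

Fitting is `scipy.optimize.least_squares` on log-parameters (positivity by
construction, no active bounds), uniform weighting by default with `1/ŷ`
and `1/ŷ²` options, ftol 1e−10. Initial values: k10 from the terminal
slope, k01 = 3·k10, V = D/(Cmax·e). Standard errors come from the
Gauss–Newton covariance on the log scale, delta-transformed. Preconditions:
≥4 points, at least one post-peak observation, not all zero.

## Indirect-response PD (`pkpd`)

Drug inhibits the zero-order production of the biomarker:

    dR/dt = Kin·(IC50/(Cp + IC50)) − Kout·R,   R(0) = Kin/Kout.

The inhibitory factor is the standard Imax = 1 form (1 at Cp = 0, ½ at
Cp = IC50, →0 at high Cp). Integration uses LSODA with rtol 1e−8 /
atol 1e−10, evaluating the solver's interpolant at the requested times
rather than forcing steps. Because the drug acts on production, the
response nadir always lags the concentration peak — the hysteresis that
distinguishes this model family from direct-effect (and from effect-
compartment link) models; only the indirect-response equations are
implemented here.

Fitting is sequential — PK parameters fixed from the prior stage, then
(Kin, Kout, IC50) estimated on log scale — matching the two-stage reporting
convention of such studies; R(0) is tied to Kin/Kout by default (the
untreated arm holds a stationary baseline over the session, supporting
this) with a free-R0 mode available. If the observed response never drops
at least 5% below baseline, or the fitted IC50 runs 50× beyond the observed
concentration range, IC50 is declared unidentifiable: the fit is flagged
and IC50 returned as NaN instead of an arbitrary large number.

With the default parameter scales (IC50 of a few ng/mL against peaks of
hundreds of ng/mL), production is almost fully suppressed for the whole
8 h window, so R decays at ≈Kout toward a low quasi-steady plateau
R ≈ Kin·IC50/(Kout·Cp(t)) and the nadir sits late in the window. IC50 is
then identified mainly by that plateau; with proportional noise this works
well (median error ≈3% in the recovery benchmark), but with an additive
noise floor above the plateau it would degrade.

## Synthetic studies (`synthetic`)

The generator emulates the study design the analysis assumes: arms
blank/model/30/60/120 mg/kg of n = 6 rats, hourly dialysate samples over
0–8 h, bench recovery at flow rates 0.5/0.8/1/2 µL/min with n = 4
replicates per condition, and an 8 h in vivo retrodialysis stability
series.

PK population defaults are calibrated to the design's observed peak:
k01 = 2·k10 makes Tmax = ln 2/k10, so k10 = ln 2/2 ≈ 0.347 /h puts the
peak at exactly 2 h and Cmax = D/(2V); V per dose is then set from the
group-mean peaks (124.5/469.3/805.9 ng/mL). Note the consequence: because
a single Bateman curve cannot peak at 2 h and also have a 0.7 h terminal
half-life, the simulated AUC and t½ are larger than the tabulated
dose-group values — the generator reproduces peak placement, not every
tabulated statistic simultaneously. PD population defaults are the per-dose
turnover estimates (Kin 523.8/556.5/272.8 pg/mL/h, Kout 0.97/1.08/0.53 /h,
IC50 0.74/2.62/1.81 ng/mL); the untreated model arm holds the mid-dose
Kin/Kout steady state (≈515 pg/mL) and the blank arm a configurable healthy
baseline of 150 pg/mL — absolute baseline levels are design choices, not
published values.

Between-subject variability is log-normal with the median at the population
value (CV 20% default); assay noise is proportional Gaussian (CV 10%
default) — dialysate assays quote precision as RSD, so noise scales with
the level — truncated at zero with a count kept on the truth record.
Quantification limits (5 ng/mL drug, 100 pg/mL biomarker) are flagged, not
censored. What passing tests on these data do **not** show: robustness to
additive noise floors, below-LOQ censoring, missing samples, or model
misspecification (multi-compartment kinetics, tolerance/rebound), none of
which the generator produces.

## Pipeline (`pipeline`, `cli`)

Defaults fit group-mean profiles (what study figures display); per-subject
mode is available. Every output CSV carries the seed and a SHA-256 hash of
the analysis configuration (output paths excluded), and reruns with the
same seed are byte-identical. Stage failures propagate with the stage name.
The CLI is a thin click wrapper with one subcommand per stage plus
`run-all`.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses 12 seeded study replicates for the simulated
design check (72 subjects), 50 replicates for the parameter-recovery
medians, and one full pipeline run for the fitted turnover parameters —
sizes chosen so the whole script completes in well under a minute on one
core while keeping Monte-Carlo error small relative to the quantities
reported.

## Known limitations

- No multi-compartment or nonlinear-elimination PK; no population
  (mixed-effects) estimation — mean-level or per-subject fits only.
- No effect-compartment (ke0 link) model; hysteresis is explained solely by
  turnover.
- NCA has no sparse-sampling or steady-state variants.
- The probe model is a single transfer fraction per condition; no membrane
  diffusion physics, no extrapolation-to-zero-flow calibration.
- IC50 units follow the fitted concentration scale (ng/mL dialysate);
  cross-study comparison requires matching that scale.
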