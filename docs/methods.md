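# Methods

## Model structure

The disposition model has three compartments: central (serum),
peripheral tissue, and CSF. Drug enters the central compartment by IV
bolus or zero-order infusion (ICV infusion into the CSF compartment is
also supported). Exchange with the peripheral compartment is governed
by the inter-compartmental clearance Cl2 (mL/h) acting on the local
concentrations; exchange with the CSF compartment by the bidirectional
flow Qcsf (mL/h). Elimination is first-order from both the central and
the CSF compartment, and both use the same clearance *value* Cl (mL/h)
applied to the local concentration: the CSF elimination **rate
constant** is therefore Cl/Vcsf, not Cl/V.

This reading of "bidirectional flow with the same clearance as the
central compartment" is a committed interpretation, chosen because it
predicts an asymptotic CSF/serum AUC ratio of Qcsf/(Qcsf + Cl) ≈ 0.21%
for the human-scale parameter set, bracketing the 0.19–0.26% exposure
ratios observed in the monkey study. The alternative reading (equal
elimination rate constants, i.e. CSF clearance Cl·Vcsf/V) predicts
roughly 0.5% and is rejected. A CSF absorption delay beyond the flow
term is not modeled.

Units are fixed package-wide: µg, mL, h, µg/mL. Weight-based doses
(mg/kg) are converted to µg at regimen construction using the regimen's
body weight.

## Solvers

The system is linear with piecewise-constant inputs, so the default
solver is exact: per dosing segment, A(t) = A_ss + e^{Mt}(A0 − A_ss)
with A_ss = −M⁻¹u, evaluated through one eigendecomposition of the 3×3
rate matrix per parameter set (reused across subjects during fitting).
When a flow parameter is exactly zero the rate matrix can be singular;
the solver then folds the input into an augmented matrix exponential.
Boluses are instantaneous amount additions. Infusion start/stop times
are inserted into output grids so peak concentrations are never
truncated between grid points.

An adaptive stiff integrator (LSODA, rtol 1e-9, atol 1e-12) solves the
same equations as an independent cross-check; the two routes agree to
≤1e-6 relative down to ~1e-8 of the profile peak, below which the
integrator's absolute tolerance dominates. Mass balance is verified by
augmenting the state with the cumulative elimination integral.

Terminal half-life is ln 2 over the slowest eigenphase carrying
nonvanishing weight in the requested compartment's bolus response
(serum and CSF share the terminal phase in this model); for
near-degenerate eigenvalues the implementation falls back to a
log-linear slope on a simulated tail and flags the result.

## Allometric scaling

Volumes scale with body weight to the exponent 1; Cl, Cl2 and Qcsf all
scale with exponent 0.8 (4.42 kg cynomolgus ↔ 80 kg human). Exponents
are configurable per parameter class but default to these values.
Only fixed effects are scaled; between-subject variances are not.
Since all clearance-like parameters share one exponent, dimensionless
ratios such as Qcsf/Cl — and hence the asymptotic CSF/serum AUC ratio —
are invariant under the projection.

## Estimation

A full nonlinear mixed-effects engine is out of scope. Two estimators
are provided:

* **Naive-pooled**: box-constrained minimization of a Gaussian
  negative log-likelihood on log concentrations over all quantifiable
  records, in log-parameter space (bounds 1e-3 to 1e7 on each
  parameter), with seeded multi-start (default 8 starts, log-normal
  jitter SD 0.5); ties broken by objective then parameter-vector norm.
  Standard errors come from a finite-difference Hessian in log space
  via the delta method.
* **Two-stage**: per-subject pooled fits, then geometric-mean typical
  values and log-normal between-subject CVs, sqrt(exp(s²) − 1) with s
  the SD of the log estimates. Non-convergent subjects are dropped
  with a warning; fewer than two usable subjects is an error.

The residual model is combined proportional + additive, expressed on
the log scale with per-point variance ln(1 + cv² + (σ_add/pred)²);
the default is proportional CV 15%, additive 0 (the study's residual
magnitudes are unreported, so these are declared package defaults).
Records flagged below the LLOQ are excluded; likelihood-based BLQ
handling is not implemented. Without CSF observations, Vcsf and Qcsf
are structurally non-identifiable: they are held at their initial
values and flagged in the result.

Naive pooling of heterogeneous subjects estimates a "typical" value
that is not exactly the geometric mean of the individual parameters;
with substantial between-subject variability the pooled estimate can
deviate from the generating typical value by roughly the
between-subject CV divided by √n plus a pooling distortion of similar
order. The two-stage estimator targets the geometric mean directly
and is preferred when per-subject data are rich enough.

## Non-compartmental analysis

Cmax/Tmax are read directly from the samples; AUC uses the linear
trapezoid throughout (a declared convention so results are bit-for-bit
reproducible). AUC is reported on [0, t_end] with t_end recorded; no
extrapolation to infinity unless requested. The terminal phase is the
last k = 3…8 positive points after the peak with the best adjusted R²
among windows with negative slope — the originating analysis does not
state its rule, so this one is declared. Model eigenphase half-lives
and NCA λz half-lives are both available and cross-checked in tests.

## Regimen simulation and target attainment

Weekly (168 h) 30-min IV infusions are simulated for a default 26-week
horizon — several terminal half-lives at human scale — by the exact
solver. Steady state requires the CSF trough to change by less than 1%
between the last two intervals; metrics (trough, peak, interval
average, first-interval peak) are then read from the last complete
interval, where residual accumulation has settled. The attainment
criterion behind any specific published dose threshold is ambiguous,
so the conservative default is trough ≥ band lower edge, with all four
metrics reported. By linearity, the minimal continuous dose is the
band edge divided by the per-unit-dose metric; the grid search result
is cross-checked against brute-force simulation in the tests.

## Assay calibration

Percent surface expression and percent inhibition are linear
normalizations between 100%/0% anchor controls, affine-invariant in
the raw signals, returned unclipped with an out-of-range flag. The
non-expressing-cell background MFI is subtracted before normalization
or curve fitting.

Standard curves are four-parameter logistic (sigmoid-Emax), fitted by
least squares in log-concentration space with multi-start; an EC50
outside the standard concentration range (or responses that never
cross the midrange) raises a "not bracketed" error. Sample responses
are inverse-calibrated through the fitted 4PL — not piecewise
interpolation — and censored (below/above) outside the quantifiable
range rather than extrapolated. Serum–CSF concordance is ordinary
least squares of CSF on serum pseudo-concentration (untransformed),
with Pearson R² and the two-sided slope t-test p-value; reported
CSF/serum ratios are rounded half-up to one decimal, matching the
published table's convention (banker's rounding would disagree on
exact ties).

## Synthetic data

The generator emulates the originating study design: two dose groups
(100 and 1000 mg/kg, 30-min IV infusion, n = 3 each), body weights
drawn around 4.42 kg (CV 7%, truncated at ±3 SD), dense serum sampling
from 5 min to 1008 h and sparse CSF sampling from 24 h to 1008 h,
log-normal between-subject variability (default CV 30% on every
structural parameter) and log-normal proportional residual error
(default CV 15%). LLOQ defaults are 1.0 µg/mL (serum) and 0.05 µg/mL
(CSF); records below are flagged, not dropped. Each subject draws from
its own stream keyed by (master seed, subject index), so a fixed seed
is byte-reproducible and adding subjects never perturbs earlier ones.
Where the originating study does not report a value (exact sampling
schedule, LLOQs, variability magnitudes), the defaults above are
declared package conventions, not inferences.

Assay plates place standards on the 10-fold reference dilution series
(10 → 0.0001 µg/mL) plus samples at requested concentrations, with
multiplicative read noise and an additive background measured by
dedicated background wells.

What the generator does *not* emulate: target-mediated (nonlinear)
disposition, assay drift or plate-position effects, correlated
between-subject random effects, and BLQ-value imputation error.
Passing recovery tests on this generator therefore demonstrates
correctness of the estimation machinery under the stated statistical
assumptions, not robustness to real-data violations of them.

## Problem sizes and numerical conventions

Simulation grids of a few thousand points resolve 1008-h profiles to
well below 0.1% trapezoid error; recovery experiments use 20 seeded
replicates of the 6-animal design; 4PL noise studies use 50 seeds.
Optimizer tie-breaks, bounds, and jitter are fixed and seeded so every
reported number is a deterministic function of (inputs, seed).
Concentrations are clipped to zero only within 1e-9 relative solver
tolerance; larger negatives raise an error rather than being masked.

## Known limitations

* Naive-pooled and two-stage estimation are not mixed-effects
  estimation; BSV estimates from the two-stage route are inflated by
  per-subject estimation noise and are reported as summaries, not as
  formal variance components.
* The terminal-phase selection rule and the trapezoid convention are
  declared, defensible defaults; other NCA software may differ in the
  second decimal.
* The model is linear: saturable FcRn recycling or target binding, if
  present at extreme doses, are outside its domain.
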