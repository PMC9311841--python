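# Methods

## Structural model and closed forms

Disposition is the linear two-compartment model with first-order
elimination from the central compartment.  All profile evaluation uses the
closed-form biexponential solution for zero-order infusion input; no ODE
integration occurs in the package (the test suite uses an adaptive ODE
solver as an independent oracle, agreeing with the closed form to 1e-6
relative over 0–12 h for randomized parameter sets).

Reparameterization: k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp; the hybrid
exponents α, β are the roots of x² − (k10+k12+k21)x + k10·k21 = 0, with β
computed as (k10·k21)/α (Vieta) for numerical stability of the small root.
The unit-bolus intercepts satisfy A + B = 1/Vc and A/α + B/β = 1/CL; both
identities are enforced in tests at 1e-9 relative over 1000 random
parameter sets.  A degenerate α ≈ β (discriminant below 1e-10 relative) is
rejected with an error rather than handled by a confluent formula — it
cannot arise for clinically distinct distribution and elimination phases.

Steady state under repeated dosing is computed analytically: each
exponential term's post-infusion decay accumulates geometrically, giving
the factor 1/(1 − e^{−λτ}); during the infusion the current dose's rising
term adds to the accumulated tail of all previous doses.  The analytic
profile matches a 10-dose explicit superposition to 1e-6 relative.  Time
grids over a dosing interval are half-open [0, τ) at step dt with the
end-of-infusion time always included as an exact grid point (the
concentration maximum lies there).

Units are fixed package-wide: mg, L, h, mg/L.  Doses in grams are
converted at the interface boundary (`DoseRegimen.from_grams`).

## Population model

Typical values CL 14.2 L/h, Vc 8.17 L, Q 8.54 L/h, Vp 6.95 L.
Between-subject variability is log-normal, Pᵢ = P_typ,i·exp(η),
η ~ N(0, ω²) independent across parameters (no correlations are modelled;
none are reported).  ω is interpreted directly as the CV (ω = CV: 0.151,
0.153, 0.0737 for CL, Vc, Vp; 0 for Q).  At these magnitudes the
alternative ω² = ln(1+CV²) differs by < 0.3% in ω and is indistinguishable
in any downstream quantity; the choice is fixed here once.

The only covariate is body weight on the peripheral volume,
Vp = 6.95·(BW/61.3)^0.713.  The reference weight 61.3 kg is the cohort mean
(not separately reported as a model constant) and is exposed in the config.

Residual error is y = c(1+ε₁) + ε₂ with ε₁ ~ N(0, 0.121²) and
ε₂ ~ N(0, add_err²), truncated at zero.  The additive term is printed in
the source model table as "3.76" under a percent header, which is
dimensionally ambiguous for an additive component; the package defaults to
add_err = 0.376 mg/L (configurable).  Note this value is nearly four times
the assay LLOQ of 0.100 mg/L, so synthetic concentrations below ~1 mg/L are
very noisy — this drives the terminal-phase behaviour discussed under
"Known limitations".  Residual error is used only when generating synthetic
observations; PK/PD simulation always uses model-predicted concentrations.

## PTA simulation

The PK/PD index is %fT>MIC with free fraction 0.915 and target fraction
0.35.  For each simulated subject the steady-state free-concentration
profile over one dosing interval is evaluated on a 0.005 h grid (chosen so
the interval-fraction error stays below 0.1%); threshold crossings are
located by linear interpolation within grid segments, which agrees with a
bisection root-finder on the exact curve to better than 0.001 of the
interval.  Strict inequality (free concentration > MIC) is used at the
threshold; the difference is measure-zero.

PTA at a MIC is the fraction of n_sim = 5000 sampled subjects attaining the
target.  A PTA curve over a MIC grid reuses one sampled population for all
MICs (common random numbers), making the curve exactly non-increasing in
MIC.  The default MIC grid is the doubling series 0.03125–32 mg/L; the
shipped default regimen set covers 0.25/0.5/1.0 g over 1 h at q12h and q8h
plus 1.0 g over 4 h q8h.

Two design points were genuinely open and are fixed as follows.  First,
whether PTA uses first-dose or steady-state profiles: steady state is the
default (the pharmacometric convention for maintenance dosing); first-dose
mode is retained via `n_doses=1`, and the difference is under 1% here
because the dosing interval is ~7 terminal half-lives.  Second, whether the
Monte Carlo population samples body weight: by default weight is held at
the 61.3 kg reference, making the covariate inert; sampling from the
truncated N(61.3, 9.71) on [45, 85] kg is available (`sample_bw=True`) and
shifts PTA by well under the Monte Carlo noise, consistent with reported
weight-stratification checks showing dosing conclusions are
weight-insensitive.

## Non-compartmental analysis

λz is estimated by log-linear least squares over terminal suffixes of the
post-Tmax samples (Tmax excluded, ≥ 3 quantifiable points), selecting the
suffix with maximal adjusted R²; ties favour more points.  A non-negative
slope yields a not-estimable flag and all ∞-extrapolated outputs are
withheld while finite-interval AUCs are still reported.

AUC uses the lin-up/log-down trapezoid (linear while concentrations rise or
tie, log while falling; exact for exponential decay), with boundary
interpolation on the same convention when 8 h or 24 h falls between
samples, and linear fallback when a zero concentration enters a falling
segment.  AUMC uses the exact first-moment formulas of the same segment
models.  AUC_0–∞ = AUC_0–last + C_last/λz; CL = dose/AUC_0–∞;
Vz = CL/λz (the "V_d" of conventional report tables); MRT subtracts
t_inf/2 by default to correct for the zero-order input (configurable, as
report conventions differ).

BLQ observations (< 0.100 mg/L) are treated as missing — dropped from λz
fitting and AUC — with no imputation; a pre-dose t = 0 sample is kept as a
structural zero so the rising segment integrates from zero.

Urine: Ae(0–24) is the sum of interval amounts (volume × concentration),
CLr = Ae(0–24)/AUC_0–24, recovery = 100·Ae/dose per interval and
cumulatively.  The dose-proportionality power model regresses ln(value) on
ln(dose) by OLS with a t-based 90% CI on the slope.

## Synthetic trial generator

The generator emulates a single-dose, four-period self-crossover study in
12 healthy adults (6 male/6 female): weight ~ N(61.3, 9.71) kg truncated to
[45, 85]; age uniform 18–45 y; serum creatinine back-solved from a target
Cockcroft–Gault clearance draw ~ N(120, 17.3) mL/min (floored at 60) so the
roster reproduces the cohort's renal function.  Each subject gets one
between-subject parameter draw shared across periods (no inter-occasion
variability is modelled; none is reported).  Plasma sampling is the
clinical schedule: pre-dose and 0.25–12 h (15 nominal times) after the
start of infusion.  Urine windows are 0–2, 2–4, 4–8, 8–12, 12–24 h for 1 h
infusions and 0–4, 4–8, 8–12, 12–24 h for the 4 h infusion.

Urinary excretion assumes a constant renal fraction fe (default 0.70, from
the observed 68–72% cumulative recovery): interval amount =
fe·CL_i·(partial AUC over the window), computed from the exact analytic
cumulative AUC, so noise-free 24 h recovery is fe minus the ~0.1% of AUC
beyond 24 h (≈ 69.9%).  Urine volume is drawn around a 0.06 L/h production
rate with 20% CV — an invented realism layer that affects urine
concentrations only, never amounts or CLr.

What the generator does **not** emulate: assay drift or stability effects,
inter-occasion variability, dropout, irregular sampling deviations, and any
correlation between renal function and drug clearance (healthy subjects'
Ccr spans a narrow range and was not a covariate in the final model).
Passing recovery tests on these data therefore show internal consistency
of the estimators under the stated error model, not robustness to the
messiness of real bioanalytical data.

## Per-subject fitting and two-stage summaries

`TwoCompartmentModel.fit()` minimizes error-model-weighted least squares,
residual (y − ŷ)/√((0.121·ŷ)² + 0.376²), over log-parameterized
(CL, Vc, Q, Vp) jointly across a subject's four administrations, using
Levenberg–Marquardt with three starts (population typicals plus two
log-normally jittered starts, SD 0.3); the best converged solution wins,
ties broken by the lower Jacobian condition number.  The log
parameterization enforces positivity.

The weighting deliberately includes the additive error term: with purely
proportional 1/ŷ² weighting, the handful of near-LLOQ terminal points —
whose noise is dominated by the 0.376 mg/L additive component and whose
surviving values are selection-biased upward by LLOQ censoring — dominate
the objective and bias clearance low by ~15%.  Weighting by the combined
error SD restores unbiased recovery (two-stage geometric-mean CL within 2%
in replicate simulations).  Setting `add_err=0` reproduces the classical
proportional scheme.

The two-stage summary reports geometric means and log-scale CVs across
converged individual fits, excluding and counting failures.  This is a
deliberate desk-scale surrogate for full nonlinear mixed-effects
estimation: it requires rich per-subject data (as this design provides)
and is expected to overstate between-subject variability slightly because
individual estimation error folds into the CV.

## Problem sizes and numerical defaults

PTA uses n = 5000 subjects per regimen/MIC (matching the simulation size
of the source analysis); parameter-recovery checks use 1000 subjects with
rich sampling (0.25 h steps to 2 h, then 0.5 h steps to 24 h); the
generator's trial size is the clinical n = 12.  The PTA grid step is
0.005 h; profile degeneracy is rejected below a 1e-10 relative
discriminant; the λz selector requires ≥ 3 points.  All random draws flow
through `numpy.random.default_rng` seeds supplied by the caller, so every
table and curve in the documentation is exactly reproducible.

## Known limitations

- On the sparse clinical schedule with LLOQ censoring, NCA clearance for
  individual subjects can deviate up to ~4–5% even noise-free (terminal
  extrapolation), and with the default residual error the 0.25 g arm's
  terminal half-life estimates are upward-biased — near the LLOQ the
  additive noise is larger than the signal and the adjusted-R² selector
  can lock onto a flat noisy tail (see the README example).  The
  `NCAResult` carries `auc_ext_pct`, `lambda_r2_adj` and
  `n_lambda_points` so downstream reports can filter such fits.
- The additive residual error's unit ambiguity (0.376 mg/L adopted) only
  affects synthetic-data realism, never PTA or any model-implied quantity.
- Nonlinear elimination, lag times, three-compartment alternatives,
  MIC-distribution-weighted response fractions and renal-impairment dose
  adjustment are out of scope.
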