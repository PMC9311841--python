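# doripk

Population pharmacokinetic/pharmacodynamic modelling and simulation of
**doripenem**, a carbapenem antibiotic given by intravenous infusion.  The
package is aimed at pharmacometricians who want to evaluate dosing regimens
against pathogens of varying susceptibility: it simulates plasma exposure
from a published-style population PK model, computes the PK/PD index that
drives carbapenem efficacy (%fT>MIC), and estimates the probability of
target attainment (PTA) by Monte Carlo simulation.  It also provides a full
non-compartmental analysis (NCA) toolkit, a synthetic crossover-trial
generator, and per-subject model fitting with two-stage population
summaries.

## The model

Disposition follows a two-compartment mammillary model with first-order
elimination, parameterized by clearance CL, central volume V_c,
inter-compartmental clearance Q and peripheral volume V_p.  Plasma
concentration during and after a zero-order infusion of rate R is the
closed-form biexponential

```
C(t) = R * Σ_i (c_i/λ_i) (1 − e^{−λ_i t})                    t ≤ t_inf
C(t) = R * Σ_i (c_i/λ_i) (1 − e^{−λ_i t_inf}) e^{−λ_i (t−t_inf)}   t > t_inf
```

with (c_i, λ_i) ∈ {(A, α), (B, β)} derived from the rate constants
k10 = CL/V_c, k12 = Q/V_c, k21 = Q/V_p.  Steady state under q8h/q12h dosing
is evaluated analytically through the geometric accumulation factor
1/(1 − e^{−λ_i τ}) per exponential term.

The population model uses typical values CL = 14.2 L/h, V_c = 8.17 L,
Q = 8.54 L/h, V_p = 6.95 L with log-normal between-subject variability
(CV 15.1%, 15.3% and 7.37% on CL, V_c, V_p; Q fixed) and one covariate:
body weight on the peripheral volume, V_p,i = 6.95·(BW/61.3)^0.713.
Observed concentrations carry combined proportional (12.1%) + additive
residual error.

A simulated subject attains the PK/PD target when the free drug
concentration (free fraction 0.915) exceeds the MIC for at least 35% of the
steady-state dosing interval; PTA at a MIC is the attaining fraction of
5000 subjects sampled from the population model.

## Worked example

```python
import numpy as np
from doripk import (PopulationModel, DoseRegimen, TwoCompartmentParams,
                    terminal_half_life, pta_curve, simulate_trial,
                    TrialDesign, nca_plasma_table)

model = PopulationModel()
typical = TwoCompartmentParams(model.tv_cl, model.tv_vc, model.tv_q, model.tv_vp)
print(f"terminal half-life: {terminal_half_life(typical):.2f} h")

regimen = DoseRegimen.from_grams(0.5, 1.0, tau=8.0, n_doses=None)  # 0.5 g/1 h q8h
curve = pta_curve(model, regimen, mic_grid=[0.25, 0.5, 1, 2, 4, 8],
                  n_sim=5000, seed=42)
for mic, pta in zip(curve.mic_grid, curve.pta):
    print(f"MIC {mic:5.2f} mg/L  PTA {100*pta:5.1f} %")

trial = simulate_trial(TrialDesign(), model, seed=7)   # 12 subjects, 4 periods
nca = nca_plasma_table(trial.plasma)
print(nca.groupby("regimen_label")[["Cmax", "AUC_0_inf", "T_half", "CL"]]
      .median().round(2))
```

prints

```
terminal half-life: 1.10 h
MIC  0.25 mg/L  PTA 100.0 %
MIC  0.50 mg/L  PTA 100.0 %
MIC  1.00 mg/L  PTA 100.0 %
MIC  2.00 mg/L  PTA  88.7 %
MIC  4.00 mg/L  PTA   9.6 %
MIC  8.00 mg/L  PTA   0.0 %
                Cmax  AUC_0_inf  T_half     CL
regimen_label
0.25g/1h       11.88      20.41    2.49  12.28
0.5g/1h        23.54      36.57    1.58  13.68
1g/1h          48.62      64.73    1.37  15.46
1g/4h          16.68      71.33    1.36  14.02
```

Reading this: the typical subject eliminates doripenem with a ~1.1 h
terminal half-life, so the standard 0.5 g q8h regimen keeps free drug above
1 mg/L long enough in essentially every simulated subject (PTA 100% at
MIC ≤ 1), loses reliability at MIC 2 (89%) and fails at MIC ≥ 4 — raising
the dose or prolonging the infusion is needed there.  The NCA table
summarizes one synthetic 12-subject trial (medians across subjects): Cmax
scales with dose for the 1 h infusions and drops sharply for the 4 h
infusion at equal dose, while clearance stays around 14 L/h.  Terminal
half-life estimates in the 0.25 g arm run high because that arm's terminal
samples sit near the 0.100 mg/L quantification limit, where residual noise
dominates — a realistic limitation of sparse low-dose NCA, discussed in
`docs/methods.md`.

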