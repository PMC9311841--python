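"""Synthetic single-dose crossover trial generator.

Emulates a randomized, open-label, self-crossover PK study in 12 healthy
adults (6 male / 6 female): four intravenous administrations per subject
(0.25, 0.5 and 1.0 g infused over 1 h, and 1.0 g infused over 4 h) with a
washout between periods, 15 plasma samples per administration (pre-dose
through 12 h) and interval urine collections to 24 h.

Plasma observations are generated from the population model (one
between-subject parameter draw per subject, shared across periods) with
combined proportional + additive residual error and LLOQ flagging.  Urine
amounts per interval equal ``CLr_i * partial AUC`` with ``CLr_i = fe *
CL_i`` (fe = fraction excreted unchanged, default 0.70); urine volumes are
drawn around a nominal 0.06 L/h production rate and only affect
concentration realism, not the excreted amounts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nca import UrineCollection
from .pk import DoseRegimen, cumulative_auc
from .population import PopulationModel, SubjectCovariates, apply_covariates

__all__ = [
    "TrialDesign",
    "TrialDataset",
    "DEFAULT_DESIGN",
    "cockcroft_gault",
    "generate_subjects",
    "simulate_trial",
]

#: plasma sampling schedule, h after start of infusion (pre-dose included)
PLASMA_TIMES = (
    0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0,
)

URINE_INTERVALS_1H = ((0.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 24.0))
URINE_INTERVALS_4H = ((0.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 24.0))


def _study_regimens() -> tuple[DoseRegimen, ...]:
    # single administrations; tau set to the 24 h observation window
    return (
        DoseRegimen.from_grams(0.25, 1.0, tau=24.0, n_doses=1),
        DoseRegimen.from_grams(0.5, 1.0, tau=24.0, n_doses=1),
        DoseRegimen.from_grams(1.0, 1.0, tau=24.0, n_doses=1),
        DoseRegimen.from_grams(1.0, 4.0, tau=24.0, n_doses=1),
    )


@dataclass(frozen=True)
class TrialDesign:
    """Study design constants for the synthetic trial."""

    n_subjects: int = 12
    regimens: tuple = field(default_factory=_study_regimens)
    washout_days: float = 7.0
    plasma_times: tuple = PLASMA_TIMES
    lloq: float = 0.100  # mg/L
    fe: float = 0.70  # fraction of dose excreted unchanged in urine
    urine_flow: float = 0.06  # nominal urine production, L/h
    urine_flow_cv: float = 0.20

    def __post_init__(self) -> None:
        t = np.asarray(self.plasma_times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("plasma sampling times must be strictly increasing")

    def urine_intervals(self, t_inf: float):
        """Urine collection schedule: the first two windows merge to 0-4 h
        for the 4 h infusion."""
        return URINE_INTERVALS_4H if t_inf >= 4.0 else URINE_INTERVALS_1H


DEFAULT_DESIGN = TrialDesign()


def cockcroft_gault(age: float, bw: float, scr: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance estimate, mL/min.

    ``(140 - age) * weight / (72 * SCr)``, multiplied by 0.85 for women;
    age in years, weight in kg, serum creatinine in mg/dL.
    """
    if scr <= 0:
        raise ValueError("serum creatinine must be positive")
    if not (bw > 0 and age >= 0):
        raise ValueError("age and body weight must be non-negative/positive")
    ccr = (140.0 - age) * bw / (72.0 * scr)
    if sex == "female":
        ccr *= 0.85
    return max(ccr, 0.0)


def _truncnorm(rng, loc, scale, lo, hi, size):
    from scipy.stats import truncnorm

    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_subjects(
    design: TrialDesign = DEFAULT_DESIGN, seed: int | np.random.Generator = 0
) -> list[SubjectCovariates]:
    """Generate the demographic roster: equal sexes, weight ~ N(61.3, 9.71)
    truncated to [45, 85] kg, age uniform on 18-45 years, and serum
    creatinine back-solved so the Cockcroft-Gault clearance reproduces the
    cohort's Ccr ~ N(120, 17.3) mL/min."""
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    n = design.n_subjects
    sexes = ["male"] * (n // 2) + ["female"] * (n - n // 2)
    bw = _truncnorm(rng, 61.3, 9.71, 45.0, 85.0, n)
    age = rng.integers(18, 46, size=n)
    ccr = rng.normal(120.0, 17.3, size=n)
    ccr = np.clip(ccr, 60.0, None)  # physiologic floor for healthy adults
    out = []
    for i in range(n):
        factor = 0.85 if sexes[i] == "female" else 1.0
        scr = factor * (140.0 - age[i]) * bw[i] / (72.0 * ccr[i])
        out.append(
            SubjectCovariates(
                body_weight=float(bw[i]),
                sex=sexes[i],
                age=float(age[i]),
                serum_creatinine=float(scr),
                ccr=float(ccr[i]),
            )
        )
    return out


@dataclass
class TrialDataset:
    """Flat tables produced by one simulated trial.

    ``plasma`` has one row per subject-administration-sample, ``urine`` one
    row per collection interval, ``dosing`` one row per administration and
    ``roster`` one row per subject; ``seed`` and ``model_config`` record
    provenance.
    """

    roster: pd.DataFrame
    dosing: pd.DataFrame
    plasma: pd.DataFrame
    urine: pd.DataFrame
    seed: int
    model_config: dict

    # ---------------- persistence ----------------
    _FILES = ("roster", "dosing", "plasma", "urine")

    def write(self, directory) -> None:
        """Write the tidy CSV tables plus a provenance JSON."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in self._FILES:
            getattr(self, name).to_csv(d / f"{name}.csv", index=False)
        with open(d / "provenance.json", "w") as fh:
            json.dump({"seed": self.seed, "model_config": self.model_config}, fh, indent=1)
        (d / "data_dictionary.md").write_text(_DATA_DICTIONARY)

    @classmethod
    def read(cls, directory) -> "TrialDataset":
        d = Path(directory)
        tables = {name: pd.read_csv(d / f"{name}.csv") for name in cls._FILES}
        with open(d / "provenance.json") as fh:
            prov = json.load(fh)
        return cls(seed=prov["seed"], model_config=prov["model_config"], **tables)

    def to_nonmem(self) -> pd.DataFrame:
        """NONMEM-style event records (ID, TIME, AMT, RATE, DV, EVID, MDV,
        CMT, BLQ + covariates), time restarting at each period."""
        cov = self.roster.set_index("subject_id")
        rows = []
        for _, dose_row in self.dosing.iterrows():
            sid, label = dose_row["subject_id"], dose_row["regimen_label"]
            base = {
                "ID": sid,
                "PERIOD": dose_row["period"],
                "REGIMEN": label,
                "WT": cov.loc[sid, "body_weight"],
                "SEX": 1 if cov.loc[sid, "sex"] == "male" else 2,
                "AGE": cov.loc[sid, "age"],
                "SCR": cov.loc[sid, "serum_creatinine"],
                "CCR": cov.loc[sid, "ccr"],
            }
            rows.append(
                base | {
                    "TIME": 0.0, "AMT": dose_row["dose_mg"],
                    "RATE": dose_row["rate_mg_h"], "DV": np.nan,
                    "EVID": 1, "MDV": 1, "CMT": 1, "BLQ": 0,
                }
            )
            obs = self.plasma[
                (self.plasma["subject_id"] == sid)
                & (self.plasma["regimen_label"] == label)
            ]
            for _, o in obs.iterrows():
                blq = int(o["blq"])
                rows.append(
                    base | {
                        "TIME": o["time_h"], "AMT": 0.0, "RATE": 0.0,
                        "DV": o["conc_mg_L"], "EVID": 0,
                        "MDV": 1 if blq else 0, "CMT": 1, "BLQ": blq,
                    }
                )
        return pd.DataFrame(rows)

    def urine_collections(self, subject_id: int, regimen_label: str) -> list[UrineCollection]:
        g = self.urine[
            (self.urine["subject_id"] == subject_id)
            & (self.urine["regimen_label"] == regimen_label)
        ].sort_values("t_start_h")
        return [
            UrineCollection(r["t_start_h"], r["t_end_h"], r["volume_L"], r["conc_mg_L"])
            for _, r in g.iterrows()
        ]


def simulate_trial(
    design: TrialDesign = DEFAULT_DESIGN,
    model: PopulationModel = PopulationModel(),
    seed: int = 0,
) -> TrialDataset:
    """Simulate the full crossover trial.

    Each subject receives one between-subject parameter draw (shared
    across the four periods, as in a self-crossover with no inter-occasion
    variability), and each administration yields a noise-free profile that
    is then perturbed by the residual-error model and flagged against the
    LLOQ.  Set ``model.without_residual_error()`` for noise-free data.
    """
    rng = np.random.default_rng(seed)
    subjects = generate_subjects(design, rng)
    from .population import sample_individuals

    params = sample_individuals(model, subjects, rng)

    roster = pd.DataFrame(
        {
            "subject_id": np.arange(1, design.n_subjects + 1),
            "body_weight": [s.body_weight for s in subjects],
            "sex": [s.sex for s in subjects],
            "age": [s.age for s in subjects],
            "serum_creatinine": [s.serum_creatinine for s in subjects],
            "ccr": [s.ccr for s in subjects],
            "CL": [p.CL for p in params],
            "Vc": [p.Vc for p in params],
            "Q": [p.Q for p in params],
            "Vp": [p.Vp for p in params],
        }
    )

    times = np.asarray(design.plasma_times)
    dosing_rows, plasma_rows, urine_rows = [], [], []
    from .pk import conc_infusion
    from .population import perturb_observation

    for i, (subj, p) in enumerate(zip(subjects, params), start=1):
        for period, reg in enumerate(design.regimens, start=1):
            label = f"{reg.dose / 1000:g}g/{reg.t_inf:g}h"
            dosing_rows.append(
                {
                    "subject_id": i,
                    "period": period,
                    "regimen_label": label,
                    "dose_mg": reg.dose,
                    "rate_mg_h": reg.rate,
                    "t_inf_h": reg.t_inf,
                    "start_day": (period - 1) * design.washout_days,
                }
            )
            true_c = np.asarray(conc_infusion(p, reg, times))
            obs_c = perturb_observation(true_c, model, rng)
            for t, c in zip(times, obs_c):
                plasma_rows.append(
                    {
                        "subject_id": i,
                        "regimen_label": label,
                        "dose_mg": reg.dose,
                        "t_inf_h": reg.t_inf,
                        "time_h": float(t),
                        "conc_mg_L": float(c),
                        "blq": bool(c < design.lloq),
                    }
                )
            # renal excretion: amount over interval = fe * CL_i * partial AUC
            clr_i = design.fe * p.CL
            for (t0, t1) in design.urine_intervals(reg.t_inf):
                amount = clr_i * (
                    cumulative_auc(p, reg, t1) - cumulative_auc(p, reg, t0)
                )
                vol_mean = design.urine_flow * (t1 - t0)
                vol = max(
                    rng.normal(vol_mean, design.urine_flow_cv * vol_mean), 0.05 * vol_mean
                )
                urine_rows.append(
                    {
                        "subject_id": i,
                        "regimen_label": label,
                        "dose_mg": reg.dose,
                        "t_start_h": t0,
                        "t_end_h": t1,
                        "volume_L": vol,
                        "conc_mg_L": amount / vol,
                        "amount_mg": amount,
                    }
                )

    return TrialDataset(
        roster=roster,
        dosing=pd.DataFrame(dosing_rows),
        plasma=pd.DataFrame(plasma_rows),
        urine=pd.DataFrame(urine_rows),
        seed=seed if isinstance(seed, int) else -1,
        model_config=model.to_config(),
    )


_DATA_DICTIONARY = """\
# Data dictionary

## roster.csv (one row per subject)
- subject_id: integer subject identifier
- body_weight: kg
- sex: male | female
- age: years
- serum_creatinine: mg/dL
- ccr: Cockcroft-Gault creatinine clearance, mL/min
- CL, Vc, Q, Vp: the subject's simulated PK parameters (L/h, L, L/h, L)

## dosing.csv (one row per administration)
- subject_id, period, regimen_label
- dose_mg: administered dose, mg
- rate_mg_h: zero-order infusion rate, mg/h
- t_inf_h: infusion duration, h
- start_day: nominal study day of the administration

## plasma.csv (one row per sample)
- subject_id, regimen_label, dose_mg, t_inf_h
- time_h: sampling time after start of infusion, h
- conc_mg_L: observed (error-perturbed) total plasma concentration, mg/L
- blq: True when conc_mg_L is below the 0.100 mg/L quantification limit

## urine.csv (one row per collection interval)
- subject_id, regimen_label, dose_mg
- t_start_h, t_end_h: collection window, h
- volume_L: urine volume, L
- conc_mg_L: urine concentration, mg/L
- amount_mg: excreted amount (= volume * concentration), mg
"""
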