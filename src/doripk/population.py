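"""Population PK model: typical values, covariates, variability, residual error.

The final population model for doripenem in healthy adults is a
two-compartment infusion model with log-normal between-subject variability
on CL, Vc and Vp (Q fixed across subjects) and a single covariate effect:
body weight enters the peripheral volume as a power law,
``Vp_i = tv_Vp * (BW_i / bw_ref)**theta_bw``.

Observed concentrations carry a combined proportional + additive residual
error, used only when generating synthetic observations (never in the
PK/PD simulations, which work with model-predicted concentrations).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
import yaml

from .pk import TwoCompartmentParams

__all__ = [
    "PopulationModel",
    "SubjectCovariates",
    "DEFAULT_MODEL",
    "apply_covariates",
    "sample_individuals",
    "perturb_observation",
]


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographic covariates for one trial subject."""

    body_weight: float  # kg
    sex: str  # "male" | "female"
    age: float  # years
    serum_creatinine: float  # mg/dL
    ccr: float  # creatinine clearance, mL/min

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValueError("body weight must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class PopulationModel:
    """Population typical values, variability and residual-error terms.

    ``bsv_*`` are between-subject coefficients of variation interpreted
    directly as the log-normal standard deviation omega (at CVs <= 15.3%
    the alternative ``omega**2 = ln(1 + CV**2)`` is indistinguishable).
    ``bsv_q`` is fixed to 0: Q is identical across subjects.

    ``prop_err`` is the proportional residual SD (fraction) and ``add_err``
    the additive residual SD in mg/L.
    """

    tv_cl: float = 14.2  # L/h
    tv_vc: float = 8.17  # L
    tv_q: float = 8.54  # L/h
    tv_vp: float = 6.95  # L
    bsv_cl: float = 0.151
    bsv_vc: float = 0.153
    bsv_vp: float = 0.0737
    bsv_q: float = 0.0
    theta_bw: float = 0.713
    bw_ref: float = 61.3  # kg, cohort mean
    prop_err: float = 0.121
    add_err: float = 0.376  # mg/L

    def __post_init__(self) -> None:
        for name in ("tv_cl", "tv_vc", "tv_q", "tv_vp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("bsv_cl", "bsv_vc", "bsv_vp", "bsv_q", "prop_err", "add_err"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- serialization: flat structured-config block ----------------------
    _CONFIG_KEYS = (
        "tv_cl", "tv_vc", "tv_q", "tv_vp",
        "bsv_cl", "bsv_vc", "bsv_vp",
        "theta_bw", "bw_ref", "prop_err", "add_err",
    )

    def to_config(self) -> dict[str, float]:
        d = asdict(self)
        return {k: d[k] for k in self._CONFIG_KEYS}

    @classmethod
    def from_config(cls, cfg: dict[str, float]) -> "PopulationModel":
        return cls(**{k: float(cfg[k]) for k in cls._CONFIG_KEYS if k in cfg})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))

    def without_residual_error(self) -> "PopulationModel":
        return replace(self, prop_err=0.0, add_err=0.0)


DEFAULT_MODEL = PopulationModel()


def apply_covariates(model: PopulationModel, cov: SubjectCovariates) -> TwoCompartmentParams:
    """Individual typical parameters after the covariate model.

    Only the peripheral volume depends on a covariate:
    ``Vp = tv_vp * (BW / bw_ref)**theta_bw``; CL, Vc and Q are the
    population typical values.
    """
    if not cov.body_weight > 0:
        raise ValueError("body weight must be positive")
    vp = model.tv_vp * (cov.body_weight / model.bw_ref) ** model.theta_bw
    return TwoCompartmentParams(CL=model.tv_cl, Vc=model.tv_vc, Q=model.tv_q, Vp=vp)


def _sample_matrix(
    model: PopulationModel,
    body_weights: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized individual parameters, one row per subject: (CL, Vc, Q, Vp)."""
    n = body_weights.size
    eta = rng.standard_normal((n, 4))
    omegas = np.array([model.bsv_cl, model.bsv_vc, model.bsv_q, model.bsv_vp])
    vp_typ = model.tv_vp * (body_weights / model.bw_ref) ** model.theta_bw
    typ = np.column_stack(
        [np.full(n, model.tv_cl), np.full(n, model.tv_vc), np.full(n, model.tv_q), vp_typ]
    )
    return typ * np.exp(eta * omegas)


def sample_individuals(
    model: PopulationModel,
    covariates: Sequence[SubjectCovariates],
    seed: int | np.random.Generator,
) -> list[TwoCompartmentParams]:
    """Draw one parameter set per subject from the population model.

    Each parameter is the individual typical value times ``exp(eta)`` with
    ``eta ~ N(0, omega**2)`` independently per parameter; Q has omega = 0 and
    is therefore identical across subjects.  Reproducible for a fixed seed.
    """
    if len(covariates) == 0:
        raise ValueError("covariates list must be non-empty")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    bw = np.array([c.body_weight for c in covariates], dtype=float)
    mat = _sample_matrix(model, bw, rng)
    return [TwoCompartmentParams(CL=r[0], Vc=r[1], Q=r[2], Vp=r[3]) for r in mat]


def perturb_observation(
    true_conc, model: PopulationModel, rng: np.random.Generator
):
    """Apply the combined residual-error model to model-predicted concentrations.

    ``y = c (1 + eps1) + eps2`` with ``eps1 ~ N(0, prop_err**2)`` and
    ``eps2 ~ N(0, add_err**2)``; negative results are truncated to 0.
    """
    c = np.asarray(true_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("true concentrations must be non-negative")
    eps1 = rng.standard_normal(c.shape) * model.prop_err
    eps2 = rng.standard_normal(c.shape) * model.add_err
    y = np.maximum(c * (1.0 + eps1) + eps2, 0.0)
    return y if np.ndim(true_conc) else float(y)
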