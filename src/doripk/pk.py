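"""Closed-form two-compartment intravenous-infusion kinetics.

The disposition model is the linear mammillary two-compartment model with
first-order elimination from the central compartment, parameterized by
clearance ``CL``, central volume ``Vc``, inter-compartmental clearance ``Q``
and peripheral volume ``Vp``.  Plasma concentration after a zero-order
infusion is a sum of two exponentials with hybrid rate constants
``alpha > beta``; all profile evaluation in this package goes through the
closed form (no ODE integration).

Units are fixed package-wide: mg, L, h, mg/L.  Doses expressed in grams at
user-facing interfaces are converted to mg at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoCompartmentParams",
    "MicroConstants",
    "DoseRegimen",
    "ConcentrationProfile",
    "derive_micro_constants",
    "conc_infusion",
    "steady_state_conc",
    "steady_state_interval_profile",
    "single_dose_interval_profile",
    "terminal_half_life",
    "model_auc_inf",
    "cumulative_auc",
]


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Structural PK parameters for one individual.

    Attributes
    ----------
    CL : float
        Elimination clearance, L/h.
    Vc : float
        Central (plasma) volume of distribution, L.
    Q : float
        Inter-compartmental clearance, L/h.
    Vp : float
        Peripheral volume of distribution, L.
    """

    CL: float
    Vc: float
    Q: float
    Vp: float

    def __post_init__(self) -> None:
        for name in ("CL", "Vc", "Q", "Vp"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class MicroConstants:
    """Micro/macro constants of the two-compartment model.

    ``k10`` is the elimination rate constant, ``k12``/``k21`` the
    distribution rate constants, ``alpha``/``beta`` the fast and slow hybrid
    disposition rate constants and ``A``/``B`` the unit-bolus intercepts
    (1/L) so that the unit-bolus response is ``A e^{-alpha t} + B e^{-beta t}``.
    """

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    A: float
    B: float


@dataclass(frozen=True)
class DoseRegimen:
    """An intravenous infusion regimen.

    Attributes
    ----------
    dose : float
        Dose per administration, mg.
    t_inf : float
        Infusion duration, h.
    tau : float
        Dosing interval, h.
    n_doses : int or None
        Number of administered doses for a finite multiple-dose regimen;
        ``1`` means single dose, ``None`` means steady state.
    """

    dose: float
    t_inf: float
    tau: float = 8.0
    n_doses: int | None = 1

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError(f"dose must be positive, got {self.dose!r}")
        if not (0 < self.t_inf <= self.tau):
            raise ValueError(
                f"need 0 < t_inf <= tau, got t_inf={self.t_inf!r}, tau={self.tau!r}"
            )
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError("n_doses must be >= 1 or None (steady state)")

    @property
    def rate(self) -> float:
        """Zero-order infusion rate, mg/h."""
        return self.dose / self.t_inf

    @property
    def steady_state(self) -> bool:
        return self.n_doses is None

    @classmethod
    def from_grams(
        cls, dose_g: float, t_inf: float, tau: float = 8.0, n_doses: int | None = 1
    ) -> "DoseRegimen":
        """Build a regimen from a dose in grams (converted to mg)."""
        return cls(dose=dose_g * 1000.0, t_inf=t_inf, tau=tau, n_doses=n_doses)

    def label(self) -> str:
        mode = "ss" if self.steady_state else f"x{self.n_doses}"
        return f"{self.dose / 1000:g}g/{self.t_inf:g}h q{self.tau:g}h ({mode})"


@dataclass
class ConcentrationProfile:
    """Paired times/concentrations for one subject-administration."""

    times: np.ndarray
    conc: np.ndarray
    regimen: DoseRegimen

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.conc)):
            raise ValueError("concentrations must be finite")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")


_DEGENERACY_RTOL = 1e-10


def derive_micro_constants(p: TwoCompartmentParams) -> MicroConstants:
    """Convert (CL, Vc, Q, Vp) to micro constants and hybrid exponents.

    ``alpha`` and ``beta`` are the roots of
    ``x**2 - (k10 + k12 + k21) x + k10 k21 = 0`` with ``alpha > beta``;
    ``A`` and ``B`` are the unit-bolus intercepts satisfying
    ``A + B = 1/Vc`` and ``A/alpha + B/beta = 1/CL``.

    Raises
    ------
    ValueError
        If parameters are invalid or the model is degenerate
        (``alpha == beta``), which cannot occur for distinct
        compartment time scales.
    """
    k10 = p.CL / p.Vc
    k12 = p.Q / p.Vc
    k21 = p.Q / p.Vp
    s = k10 + k12 + k21
    prod = k10 * k21
    disc = s * s - 4.0 * prod
    if disc <= _DEGENERACY_RTOL * s * s:
        raise ValueError("degenerate model: alpha ~= beta is not supported")
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = prod / alpha  # Vieta: numerically stable for the small root
    A = (alpha - k21) / (p.Vc * (alpha - beta))
    B = (k21 - beta) / (p.Vc * (alpha - beta))
    return MicroConstants(k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta, A=A, B=B)


def _single_dose_terms(m: MicroConstants, regimen: DoseRegimen, t: np.ndarray) -> np.ndarray:
    """Single-dose infusion concentration at times ``t`` (t<0 -> 0)."""
    R = regimen.rate
    out = np.zeros_like(t, dtype=float)
    for c, lam in ((m.A, m.alpha), (m.B, m.beta)):
        coef = R * c / lam
        during = t <= regimen.t_inf
        tt = np.where(t > 0, t, 0.0)
        term = np.where(
            during,
            coef * -np.expm1(-lam * tt),
            coef * -np.expm1(-lam * regimen.t_inf) * np.exp(-lam * (tt - regimen.t_inf)),
        )
        out += np.where(t >= 0, term, 0.0)
    return out


def conc_infusion(p: TwoCompartmentParams, regimen: DoseRegimen, t) -> np.ndarray | float:
    """Total plasma concentration at time(s) ``t`` after the first dose.

    During the infusion the concentration is
    ``R * sum_i (c_i/lambda_i) (1 - e^{-lambda_i t})`` and after it each term
    decays from its end-of-infusion value; multiple doses (``n_doses > 1``)
    are superposed as time-shifted single-dose curves.  ``t`` is measured
    from the start of the first infusion.

    Raises
    ------
    ValueError
        For negative ``t`` or a steady-state regimen (use
        :func:`steady_state_conc` for that).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if regimen.steady_state:
        raise ValueError("conc_infusion needs a finite number of doses")
    m = derive_micro_constants(p)
    out = np.zeros_like(t_arr, dtype=float)
    for k in range(regimen.n_doses):
        out += _single_dose_terms(m, regimen, t_arr - k * regimen.tau)
    out = np.maximum(out, 0.0)
    return out if np.ndim(t) else float(out)


def steady_state_conc(p: TwoCompartmentParams, regimen: DoseRegimen, t) -> np.ndarray | float:
    """Steady-state concentration at time(s) ``t`` within the dosing interval.

    Obtained analytically: the post-infusion decay of each exponential term
    accumulates geometrically over doses, contributing the factor
    ``1/(1 - e^{-lambda tau})``; during the infusion the current dose's
    rising term adds to the accumulated tail of all previous doses.
    ``t`` is taken modulo ``tau``.
    """
    t_arr = np.mod(np.asarray(t, dtype=float), regimen.tau)
    m = derive_micro_constants(p)
    R = regimen.rate
    t_inf, tau = regimen.t_inf, regimen.tau
    out = np.zeros_like(t_arr, dtype=float)
    for c, lam in ((m.A, m.alpha), (m.B, m.beta)):
        coef = R * c / lam
        acc = 1.0 / -np.expm1(-lam * tau)
        eoi = -np.expm1(-lam * t_inf)  # 1 - e^{-lam t_inf}
        during = t_arr <= t_inf
        # previous doses: tail of the end-of-infusion value, summed over k>=1
        prev = coef * eoi * np.exp(-lam * (t_arr + tau - t_inf)) * acc
        term = np.where(
            during,
            coef * -np.expm1(-lam * t_arr) + prev,
            coef * eoi * np.exp(-lam * (t_arr - t_inf)) * acc,
        )
        out += term
    return out if np.ndim(t) else float(out)


def _interval_grid(tau: float, t_inf: float, dt: float) -> np.ndarray:
    """Half-open grid [0, tau) at step dt with t_inf included exactly."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = np.arange(0.0, tau, dt)
    if t_inf < tau and not np.any(np.isclose(grid, t_inf, rtol=0.0, atol=1e-12)):
        grid = np.sort(np.append(grid, t_inf))
    return grid


def steady_state_interval_profile(
    p: TwoCompartmentParams, regimen: DoseRegimen, dt: float = 0.005
) -> ConcentrationProfile:
    """Steady-state profile over one dosing interval ``[0, tau)``.

    The grid covers ``[0, tau)`` at step ``dt`` and always contains the
    end-of-infusion time as an exact point.
    """
    grid = _interval_grid(regimen.tau, regimen.t_inf, dt)
    conc = steady_state_conc(p, regimen, grid)
    return ConcentrationProfile(times=grid, conc=np.asarray(conc), regimen=regimen)


def single_dose_interval_profile(
    p: TwoCompartmentParams, regimen: DoseRegimen, dt: float = 0.005
) -> ConcentrationProfile:
    """First-dose profile over ``[0, tau)`` on the same grid convention."""
    grid = _interval_grid(regimen.tau, regimen.t_inf, dt)
    one = DoseRegimen(regimen.dose, regimen.t_inf, regimen.tau, n_doses=1)
    conc = conc_infusion(p, one, grid)
    return ConcentrationProfile(times=grid, conc=np.asarray(conc), regimen=regimen)


def terminal_half_life(p: TwoCompartmentParams) -> float:
    """Model-implied terminal half-life ``ln 2 / beta``, h."""
    return math.log(2.0) / derive_micro_constants(p).beta


def model_auc_inf(p: TwoCompartmentParams, dose: float) -> float:
    """Closed-form total exposure after a single dose: ``dose / CL``, mg*h/L."""
    if not dose > 0:
        raise ValueError("dose must be positive")
    return dose / p.CL


def cumulative_auc(p: TwoCompartmentParams, regimen: DoseRegimen, t: float) -> float:
    """Exact single-dose cumulative AUC from 0 to ``t`` (``t=inf`` allowed).

    Integrates the closed-form infusion curve term by term; used for urine
    amount generation (renal excretion proportional to plasma exposure) and
    as a quadrature-free exposure oracle.
    """
    if regimen.steady_state or (regimen.n_doses or 1) != 1:
        raise ValueError("cumulative_auc is defined for a single dose")
    if t < 0:
        raise ValueError("time must be non-negative")
    m = derive_micro_constants(p)
    R = regimen.rate
    t_inf = regimen.t_inf
    total = 0.0
    for c, lam in ((m.A, m.alpha), (m.B, m.beta)):
        coef = R * c / lam
        if t <= t_inf:
            total += coef * (t - (-math.expm1(-lam * t)) / lam)
        else:
            # full infusion part + post-infusion decay of the EOI value
            total += coef * (t_inf - (-math.expm1(-lam * t_inf)) / lam)
            eoi = -math.expm1(-lam * t_inf)
            if math.isinf(t):
                total += coef * eoi / lam
            else:
                total += coef * eoi * (-math.expm1(-lam * (t - t_inf))) / lam
    return total
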