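"""Non-compartmental analysis of plasma profiles and urine collections.

Implements the standard NCA parameter set for a single intravenous
infusion — Cmax/Tmax, partial and extrapolated AUC by the lin-up/log-down
trapezoid, terminal slope (lambda_z) by best-adjusted-R2 log-linear
regression, CL, Vz and MRT — plus urinary recovery / renal clearance from
interval urine collections, and the power model for dose proportionality.

Concentrations below the assay's lower limit of quantification (LLOQ,
0.100 mg/L for doripenem) are treated as missing: dropped from the
lambda_z fit and from AUC segments.  A pre-dose sample at t = 0 is kept as
a structural zero so the rising segment of the infusion is integrated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LLOQ",
    "LambdaZFit",
    "NCAResult",
    "UrineCollection",
    "UrineNCAResult",
    "PowerModelResult",
    "fit_lambda_z",
    "auc_trapezoid",
    "nca_plasma",
    "nca_urine",
    "fraction_excreted_pct",
    "power_model",
    "nca_plasma_table",
]

#: assay lower limit of quantification, mg/L
LLOQ = 0.100


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float | None  # 1/h; None when not estimable
    t_half: float | None  # h
    r2_adj: float | None
    n_points: int
    estimable: bool


@dataclass(frozen=True)
class NCAResult:
    """Plasma NCA parameters for one subject-administration.

    Infinity-extrapolated fields are ``None`` when the terminal slope is
    not estimable; finite-interval AUCs are always reported.
    """

    cmax: float  # mg/L
    tmax: float  # h
    auc_0_last: float  # mg*h/L
    auc_0_8: float | None
    auc_0_24: float | None
    auc_0_inf: float | None
    auc_ext_pct: float | None  # %
    lambda_z: float | None  # 1/h
    t_half: float | None  # h
    mrt: float | None  # h
    cl: float | None  # L/h
    vz: float | None  # L
    n_lambda_points: int
    lambda_r2_adj: float | None


@dataclass(frozen=True)
class UrineCollection:
    """One timed urine collection interval."""

    t_start: float  # h
    t_end: float  # h
    volume: float  # L
    conc: float  # mg/L

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("collection end must be after start")
        if not self.volume > 0:
            raise ValueError("urine volume must be positive")
        if self.conc < 0:
            raise ValueError("urine concentration must be non-negative")

    @property
    def amount(self) -> float:
        """Amount excreted in the interval, mg."""
        return self.volume * self.conc


@dataclass(frozen=True)
class UrineNCAResult:
    """Urinary excretion summary for one subject-administration."""

    ae_0_24: float  # mg
    clr: float | None  # L/h; None when AUC not available
    interval_recovery_pct: tuple  # % of dose per interval
    cumulative_recovery_pct: tuple  # non-decreasing, % of dose
    interval_conc: tuple  # mg/L per interval
    intervals: tuple  # (t_start, t_end) pairs


@dataclass(frozen=True)
class PowerModelResult:
    """Dose-proportionality power model ln(value) = intercept + slope*ln(dose)."""

    slope: float
    intercept: float
    ci_low: float  # 90% CI of the slope
    ci_high: float
    n_used: int
    n_excluded: int


# --------------------------------------------------------------------------
# terminal slope


def fit_lambda_z(times, conc, lloq: float = LLOQ) -> LambdaZFit:
    """Estimate the terminal elimination rate constant lambda_z.

    Log-linear least squares over the terminal points: among all suffixes
    of the post-Tmax samples with at least 3 quantifiable points (Tmax
    itself excluded), the suffix maximizing the adjusted R2 is selected.
    A non-negative slope, or fewer than 3 usable points, yields a
    not-estimable result.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    i_max = int(np.argmax(c))
    mask = (np.arange(t.size) > i_max) & (c >= lloq) & (c > 0)
    tt, cc = t[mask], c[mask]
    if tt.size < 3:
        return LambdaZFit(None, None, None, 0, False)
    logc = np.log(cc)
    best = None
    for start in range(tt.size - 2):
        x, y = tt[start:], logc[start:]
        n = x.size
        res = stats.linregress(x, y)
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        # ties broken toward more points (earlier start wins)
        if best is None or r2_adj > best[0] + 1e-12:
            best = (r2_adj, -res.slope, n)
    if best is None:
        return LambdaZFit(None, None, None, 0, False)
    r2_adj, lam, n = best
    return LambdaZFit(lam, math.log(2.0) / lam, r2_adj, n, True)


# --------------------------------------------------------------------------
# trapezoidal integration (lin-up/log-down)


def _segment_is_log(c1: float, c2: float) -> bool:
    return c2 < c1 and c1 > 0 and c2 > 0


def _segment_auc(t1, t2, c1, c2) -> float:
    dt = t2 - t1
    if _segment_is_log(c1, c2):
        return (c1 - c2) / math.log(c1 / c2) * dt
    return 0.5 * (c1 + c2) * dt


def _segment_aumc(t1, t2, c1, c2) -> float:
    dt = t2 - t1
    if _segment_is_log(c1, c2):
        k = math.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        return t1 * auc + c1 * (1.0 - (1.0 + k * dt) * math.exp(-k * dt)) / k**2
    # linear C(t): exact first moment of the trapezoid
    return dt * (2 * t1 * c1 + t1 * c2 + t2 * c1 + 2 * t2 * c2) / 6.0


def _interp_conc(t1, t2, c1, c2, t) -> float:
    """Interpolate within a segment: log for falling segments, else linear."""
    if _segment_is_log(c1, c2):
        k = math.log(c1 / c2) / (t2 - t1)
        return c1 * math.exp(-k * (t - t1))
    return c1 + (c2 - c1) * (t - t1) / (t2 - t1)


def auc_trapezoid(times, conc, t_start: float, t_end: float) -> float:
    """Partial AUC between ``t_start`` and ``t_end`` (lin-up/log-down).

    Boundaries falling between samples are handled by exact interpolation
    on the same lin-up/log-down convention.  Both boundaries must lie in
    the sampled range.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if not t_start < t_end:
        raise ValueError("need t_start < t_end")
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise ValueError("requested range extends beyond the sampled range")
    total = 0.0
    for i in range(t.size - 1):
        a, b = t[i], t[i + 1]
        lo, hi = max(a, t_start), min(b, t_end)
        if hi <= lo:
            continue
        ca = _interp_conc(a, b, c[i], c[i + 1], lo)
        cb = _interp_conc(a, b, c[i], c[i + 1], hi)
        total += _segment_auc(lo, hi, ca, cb)
    return total


def _aumc_0_last(t: np.ndarray, c: np.ndarray) -> float:
    return sum(
        _segment_aumc(t[i], t[i + 1], c[i], c[i + 1]) for i in range(t.size - 1)
    )


# --------------------------------------------------------------------------
# plasma NCA


def nca_plasma(
    times,
    conc,
    dose: float,
    t_inf: float,
    lloq: float = LLOQ,
    mrt_infusion_correction: bool = True,
) -> NCAResult:
    """Full plasma NCA for a single intravenous infusion.

    Parameters
    ----------
    times, conc : array-like
        Sampling times (h) and total plasma concentrations (mg/L).
    dose : float
        Administered dose, mg.
    t_inf : float
        Infusion duration, h.
    lloq : float
        Quantification limit; lower observations are treated as missing
        (a t = 0 pre-dose zero is kept as a structural zero).
    mrt_infusion_correction : bool
        Subtract ``t_inf/2`` from AUMC/AUC to correct the mean residence
        time for the zero-order input (on by default).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    keep = (c >= lloq) | (t == 0)
    t, c = t[keep], c[keep]
    c = np.where(t == 0, np.where(c < lloq, 0.0, c), c)
    if t.size < 3 or np.all(c == 0):
        raise ValueError("too few quantifiable observations for NCA")

    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    t_last = float(t[-1])
    auc_last = auc_trapezoid(t, c, t[0], t_last)
    auc_8 = auc_trapezoid(t, c, t[0], 8.0) if t_last >= 8.0 else None
    auc_24 = auc_trapezoid(t, c, t[0], 24.0) if t_last >= 24.0 else None

    lz = fit_lambda_z(t, c, lloq=lloq)
    if not lz.estimable:
        return NCAResult(
            cmax=cmax, tmax=tmax, auc_0_last=auc_last, auc_0_8=auc_8,
            auc_0_24=auc_24, auc_0_inf=None, auc_ext_pct=None, lambda_z=None,
            t_half=None, mrt=None, cl=None, vz=None, n_lambda_points=0,
            lambda_r2_adj=None,
        )
    clast = float(c[-1])
    tail = clast / lz.lambda_z
    auc_inf = auc_last + tail
    aumc_inf = _aumc_0_last(t, c) + clast * t_last / lz.lambda_z + clast / lz.lambda_z**2
    cl = dose / auc_inf
    mrt = aumc_inf / auc_inf - (t_inf / 2.0 if mrt_infusion_correction else 0.0)
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_last=auc_last,
        auc_0_8=auc_8,
        auc_0_24=auc_24,
        auc_0_inf=auc_inf,
        auc_ext_pct=100.0 * tail / auc_inf,
        lambda_z=lz.lambda_z,
        t_half=lz.t_half,
        mrt=mrt,
        cl=cl,
        vz=cl / lz.lambda_z,
        n_lambda_points=lz.n_points,
        lambda_r2_adj=lz.r2_adj,
    )


# --------------------------------------------------------------------------
# urine


def nca_urine(collections, auc_0_24: float | None, dose: float) -> UrineNCAResult:
    """Urinary recovery and renal clearance from interval collections.

    ``CLr = Ae(0-24)/AUC(0-24)``; recovery is the excreted amount as a
    percentage of the dose, reported per interval and cumulatively.
    Collections must not overlap.
    """
    cols = sorted(collections, key=lambda u: u.t_start)
    for a, b in zip(cols, cols[1:]):
        if b.t_start < a.t_end - 1e-9:
            raise ValueError(
                f"overlapping urine collections: ({a.t_start}, {a.t_end}) and "
                f"({b.t_start}, {b.t_end})"
            )
    amounts = np.array([u.amount for u in cols])
    ae = float(amounts.sum())
    interval_pct = tuple(100.0 * amounts / dose)
    cum_pct = tuple(np.cumsum(amounts) * 100.0 / dose)
    clr = None if auc_0_24 is None else (ae / auc_0_24 if auc_0_24 > 0 else None)
    if ae == 0:
        clr = 0.0
    return UrineNCAResult(
        ae_0_24=ae,
        clr=clr,
        interval_recovery_pct=interval_pct,
        cumulative_recovery_pct=cum_pct,
        interval_conc=tuple(u.conc for u in cols),
        intervals=tuple((u.t_start, u.t_end) for u in cols),
    )


def fraction_excreted_pct(clr: float, cl: float) -> float:
    """Fraction of the dose excreted unchanged in urine, %: ``100 * CLr / CL``."""
    if not cl > 0:
        raise ValueError("CL must be positive")
    return 100.0 * clr / cl


# --------------------------------------------------------------------------
# dose proportionality


def power_model(doses, values, alpha: float = 0.10) -> PowerModelResult:
    """Dose-proportionality power model with a 90% CI on the slope.

    Ordinary least squares of ``ln(value)`` on ``ln(dose)``; a slope of 1
    indicates exact dose proportionality.  Non-positive values are excluded
    (with a warning).
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = (d > 0) & (v > 0)
    n_excl = int((~ok).sum())
    if n_excl:
        warnings.warn(f"power_model: excluded {n_excl} non-positive observations")
    d, v = d[ok], v[ok]
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct dose levels")
    X = sm.add_constant(np.log(d))
    fit = sm.OLS(np.log(v), X).fit()
    slope = float(fit.params[1])
    if fit.df_resid > 0 and fit.bse[1] > 0:
        ci = fit.conf_int(alpha=alpha)
        lo, hi = float(ci[1][0]), float(ci[1][1])
    else:  # saturated or perfect fit: zero-width interval
        lo = hi = slope
    return PowerModelResult(
        slope=slope,
        intercept=float(fit.params[0]),
        ci_low=lo,
        ci_high=hi,
        n_used=int(d.size),
        n_excluded=n_excl,
    )


# --------------------------------------------------------------------------
# table-level wrapper


def nca_plasma_table(plasma: pd.DataFrame, lloq: float = LLOQ) -> pd.DataFrame:
    """Run plasma NCA per subject-administration from a tidy table.

    Expects columns ``subject_id, regimen_label, dose_mg, t_inf_h, time_h,
    conc_mg_L``; returns one row per (subject, regimen) with the NCA
    parameter set, column names following the conventional report layout.
    """
    rows = []
    for (sid, label), g in plasma.groupby(["subject_id", "regimen_label"], sort=True):
        g = g.sort_values("time_h")
        res = nca_plasma(
            g["time_h"].to_numpy(),
            g["conc_mg_L"].to_numpy(),
            dose=float(g["dose_mg"].iloc[0]),
            t_inf=float(g["t_inf_h"].iloc[0]),
            lloq=lloq,
        )
        rows.append(
            {
                "subject_id": sid,
                "regimen_label": label,
                "Cmax": res.cmax,
                "Tmax": res.tmax,
                "AUC_0_8h": res.auc_0_8,
                "AUC_0_24h": res.auc_0_24,
                "AUC_0_inf": res.auc_0_inf,
                "AUC_ext_pct": res.auc_ext_pct,
                "T_half": res.t_half,
                "MRT": res.mrt,
                "CL": res.cl,
                "Vd": res.vz,
                "lambda_z": res.lambda_z,
                "n_lambda_points": res.n_lambda_points,
            }
        )
    return pd.DataFrame(rows)
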