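"""Independent oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: eigenvalues
come from a generic eigensolver, profiles from adaptive ODE integration,
exposures from adaptive quadrature, and threshold crossings from bisection.
"""

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq


def eigen_exponents(CL, Vc, Q, Vp):
    """Hybrid rate constants (alpha, beta) via the 2x2 rate matrix."""
    k10, k12, k21 = CL / Vc, Q / Vc, Q / Vp
    M = np.array([[-(k10 + k12), k21], [k12, -k21]])
    ev = np.sort(np.linalg.eigvals(M).real)
    return -ev[0], -ev[1]  # alpha (fast), beta (slow)


def ode_conc(CL, Vc, Q, Vp, dose, t_inf, times, n_doses=1, tau=None):
    """Two-compartment infusion concentrations by adaptive ODE integration."""
    k10, k12, k21 = CL / Vc, Q / Vc, Q / Vp
    rate = dose / t_inf

    def rhs(t, y):
        r = 0.0
        for k in range(n_doses):
            start = k * (tau or 0.0)
            if start <= t < start + t_inf:
                r = rate
                break
        return [r - (k10 + k12) * y[0] + k21 * y[1], k12 * y[0] - k21 * y[1]]

    # break integration at every infusion switch point for accuracy
    switches = []
    for k in range(n_doses):
        start = k * (tau or 0.0)
        switches += [start, start + t_inf]
    t_eval = np.asarray(times, dtype=float)
    t_end = max(t_eval.max(), max(switches))
    sol = solve_ivp(
        rhs, (0.0, t_end), [0.0, 0.0], t_eval=t_eval, rtol=1e-11, atol=1e-14,
        max_step=min(t_inf, 0.5), method="LSODA",
    )
    assert sol.success
    return sol.y[0] / Vc


def quad_auc(conc_fn, t_end, tail_rate=None, tail_c=None):
    """Adaptive-quadrature AUC to t_end, plus an exponential tail if given."""
    auc, _ = quad(conc_fn, 0.0, t_end, limit=500)
    if tail_rate is not None:
        auc += tail_c / tail_rate
    return auc


def bisection_time_above(conc_fn, thresh, t_end, n_scan=4000):
    """Time with conc_fn(t) > thresh on [0, t_end], crossings by brentq."""
    ts = np.linspace(0.0, t_end, n_scan)
    vals = np.array([conc_fn(t) - thresh for t in ts])
    crossings = []
    for a, b, va, vb in zip(ts[:-1], ts[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            crossings.append(a)
        elif va * vb < 0:
            crossings.append(brentq(lambda t: conc_fn(t) - thresh, a, b, xtol=1e-12))
    above = vals[0] > 0
    total, t_prev = 0.0, 0.0
    for c in crossings:
        if above:
            total += c - t_prev
        above, t_prev = not above, c
    if above:
        total += t_end - t_prev
    return total
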