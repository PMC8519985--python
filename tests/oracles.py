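"""Independent oracles used by the test suite.

Each oracle reaches the quantity under test by a different route than the
package (direct ODE integration, brute-force enumeration, generic
high-precision optimisation), so agreement is evidence of correctness
rather than self-confirmation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import minimize
from scipy.stats import rankdata


def ode_f2tc_irf(p, t_seconds):
    """F2TC impulse response past the vascular window via the compartment ODEs.

    Integrates dC1/dt = -(k2+k3) C1 + k4 C2, dC2/dt = k3 C1 - k4 C2 with
    C1(0) = K1, C2(0) = 0 (time in minutes) and returns K1-normalised total
    tissue response H(t') = C1 + C2 at t' = t_seconds past the window.
    """
    t_min = np.atleast_1d(np.asarray(t_seconds, dtype=float)) / 60.0

    def rhs(_, c):
        c1, c2 = c
        return [-(p.k2 + p.k3) * c1 + p.k4 * c2, p.k3 * c1 - p.k4 * c2]

    sol = solve_ivp(rhs, (0.0, max(t_min.max(), 1e-9)), [p.K1, 0.0],
                    method="Radau", rtol=1e-11, atol=1e-14, dense_output=True)
    return sol.sol(t_min).sum(axis=0)


def ode_f2tc_forward(p, aif_callable, schedule, dt_fine=0.1):
    """Frame-averaged F2TC tissue curve via driven ODEs plus quadrature.

    The vascular term is the running-integral difference of the input; the
    tissue term integrates the two-compartment ODEs driven by the delayed
    input.  Entirely independent of the package's recursive convolution.
    """
    t_end = schedule.span_end
    tf = np.arange(0.0, t_end + dt_fine / 2, dt_fine)
    a = aif_callable(tf)
    A = cumulative_trapezoid(a, tf, initial=0.0)
    d = p.t0 + p.W
    vasc = (p.F / 60.0) * (np.interp(tf - p.t0, tf, A, left=0.0)
                           - np.interp(tf - d, tf, A, left=0.0))

    def rhs(t, c):
        ca = np.interp(t - d, tf, a, left=0.0)
        c1, c2 = c
        return [(p.K1 * ca - (p.k2 + p.k3) * c1 + p.k4 * c2) / 60.0,
                (p.k3 * c1 - p.k4 * c2) / 60.0]

    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], method="LSODA",
                    rtol=1e-10, atol=1e-13, dense_output=True, max_step=5.0)
    tissue = sol.sol(tf).sum(axis=0)
    total = vasc + tissue
    out = []
    for s, e in zip(schedule.start, schedule.end):
        m = (tf >= s - 1e-9) & (tf <= e + 1e-9)
        out.append(np.trapezoid(total[m], tf[m]) / (e - s))
    return np.array(out)


def ode_ath_forward(p, aif_callable, schedule, dt_fine=0.05):
    """Frame-averaged ATH enhancement via quadrature plus a driven ODE."""
    t_end = schedule.span_end
    tf = np.arange(0.0, t_end + dt_fine / 2, dt_fine)
    a = aif_callable(tf)
    A = cumulative_trapezoid(a, tf, initial=0.0)
    d = p.t0 + p.Tc
    box = (np.interp(tf - p.t0, tf, A, left=0.0)
           - np.interp(tf - d, tf, A, left=0.0))
    if p.E > 0:
        k = p.E * p.BF / (60.0 * p.Ve)

        def rhs(t, y):
            return [p.E * np.interp(t - d, tf, a, left=0.0) - k * y[0]]

        sol = solve_ivp(rhs, (0.0, t_end), [0.0], method="LSODA",
                        rtol=1e-10, atol=1e-13, dense_output=True, max_step=2.0)
        tail = sol.sol(tf)[0]
    else:
        tail = np.zeros_like(tf)
    total = (p.BF / 6000.0) * (box + tail)
    out = []
    for s, e in zip(schedule.start, schedule.end):
        m = (tf >= s - 1e-9) & (tf <= e + 1e-9)
        out.append(np.trapezoid(total[m], tf[m]) / (e - s))
    return np.array(out)


def brute_wilcoxon(diffs):
    """Two-sided signed-rank p by exhaustive sign enumeration (n <= ~14)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def newton_logistic(X, y, tol=1e-12):
    """Logistic ML coefficients via generic high-precision minimisation."""
    X = np.column_stack([np.ones(len(X)), X])

    def nll(b):
        eta = X @ b
        return -(y @ eta - np.logaddexp(0.0, eta).sum())

    def grad(b):
        eta = np.clip(X @ b, -700, 700)
        mu = 1.0 / (1.0 + np.exp(-eta))
        return -(X.T @ (y - mu))

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": tol, "maxiter": 5000})
    return res.x


def brute_auc(scores, labels):
    """AUC by exhaustive pairwise comparison, ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
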