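"""Numba kernel: per-branch adaptive integration of the BiSSE ODE system.

State vector along a branch is ``(E0, E1, D0, D1)`` in time-before-present
coordinates: ``E_s(t)`` is the probability that a single lineage in state
``s`` alive at time ``t`` leaves no sampled descendant at the present;
``D_s(t)`` is the likelihood of the observed clade subtending the branch
given the lineage is in state ``s`` at ``t``.

    E0' = mu0 - (lam0+mu0+q01) E0 + q01 E1 + lam0 E0^2
    D0' =     - (lam0+mu0+q01) D0 + q01 D1 + 2 lam0 E0 D0       (0 <-> 1 sym.)

Integration uses an embedded Cash-Karp 4(5) pair with standard PI-free
step control.  ``D`` is renormalized at the top of every branch and the
log scale accumulated, so 1000-tip trees do not underflow.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_MAXSTEPS = 2

_MAX_STEPS_PER_BRANCH = 100_000


@njit(cache=True, inline="always")
def _deriv(y, pars, dy):
    l0, m0, q01, l1, m1, q10 = pars[0], pars[1], pars[2], pars[3], pars[4], pars[5]
    e0, e1, d0, d1 = y[0], y[1], y[2], y[3]
    dy[0] = m0 - (l0 + m0 + q01) * e0 + q01 * e1 + l0 * e0 * e0
    dy[1] = m1 - (l1 + m1 + q10) * e1 + q10 * e0 + l1 * e1 * e1
    dy[2] = -(l0 + m0 + q01) * d0 + q01 * d1 + 2.0 * l0 * e0 * d0
    dy[3] = -(l1 + m1 + q10) * d1 + q10 * d0 + 2.0 * l1 * e1 * d1


@njit(cache=True)
def _integrate_branch(y, t0, t1, pars, rtol, atol, diag):
    """Advance y in place from t0 to t1 (t1 > t0). Returns status."""
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    k5 = np.empty(4)
    k6 = np.empty(4)
    ytmp = np.empty(4)
    y5 = np.empty(4)

    t = t0
    h = (t1 - t0) * 0.1
    nstep = 0
    while t < t1:
        if h > t1 - t:
            h = t1 - t
        _deriv(y, pars, k1)
        for i in range(4):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _deriv(ytmp, pars, k2)
        for i in range(4):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _deriv(ytmp, pars, k3)
        for i in range(4):
            ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _deriv(ytmp, pars, k4)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                -11.0 / 54.0 * k1[i] + 2.5 * k2[i]
                - 70.0 / 27.0 * k3[i] + 35.0 / 27.0 * k4[i]
            )
        _deriv(ytmp, pars, k5)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                1631.0 / 55296.0 * k1[i] + 175.0 / 512.0 * k2[i]
                + 575.0 / 13824.0 * k3[i] + 44275.0 / 110592.0 * k4[i]
                + 253.0 / 4096.0 * k5[i]
            )
        _deriv(ytmp, pars, k6)

        errmax = 0.0
        for i in range(4):
            y5[i] = y[i] + h * (
                37.0 / 378.0 * k1[i] + 250.0 / 621.0 * k3[i]
                + 125.0 / 594.0 * k4[i] + 512.0 / 1771.0 * k6[i]
            )
            y4i = y[i] + h * (
                2825.0 / 27648.0 * k1[i] + 18575.0 / 48384.0 * k3[i]
                + 13525.0 / 55296.0 * k4[i] + 277.0 / 14336.0 * k5[i]
                + 0.25 * k6[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(y5[i] - y4i) / sc
            if e > errmax:
                errmax = e
        if not np.isfinite(errmax):
            return STATUS_NONFINITE
        if errmax <= 1.0:
            t += h
            for i in range(4):
                y[i] = y5[i]
            if y[0] < diag[0]:
                diag[0] = y[0]
            if y[1] < diag[0]:
                diag[0] = y[1]
            if y[0] > diag[1]:
                diag[1] = y[0]
            if y[1] > diag[1]:
                diag[1] = y[1]
            if y[2] < diag[2]:
                diag[2] = y[2]
            if y[3] < diag[2]:
                diag[2] = y[3]
        # step-size update (5th-order controller)
        if errmax > 1e-30:
            fac = 0.9 * errmax ** (-0.2)
        else:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h *= fac
        nstep += 1
        if nstep > _MAX_STEPS_PER_BRANCH:
            return STATUS_MAXSTEPS
    return STATUS_OK


@njit(cache=True)
def bisse_postorder(parent, left, right, age, post_internal, tip_state,
                    pars, rtol, atol):
    """Post-order BiSSE pass over the whole tree.

    Returns (root_y, logscale, status, failed_node, diag) where root_y is
    the (E0,E1,D0,D1) vector after combining at the root (speciation factor
    applied) and diag = [minE, maxE, minD] over the integration.
    """
    n = parent.shape[0]
    vals = np.zeros((n, 4))
    for i in range(n):
        if left[i] < 0:
            if tip_state[i] == 0:
                vals[i, 2] = 1.0
            else:
                vals[i, 3] = 1.0
    logscale = 0.0
    diag = np.zeros(3)
    diag[2] = np.inf
    yl = np.empty(4)
    yr = np.empty(4)
    for idx in range(post_internal.shape[0]):
        v = post_internal[idx]
        cl = left[v]
        cr = right[v]
        for i in range(4):
            yl[i] = vals[cl, i]
            yr[i] = vals[cr, i]
        status = _integrate_branch(yl, age[cl], age[v], pars, rtol, atol, diag)
        if status != STATUS_OK:
            return vals[v], logscale, status, cl, diag
        status = _integrate_branch(yr, age[cr], age[v], pars, rtol, atol, diag)
        if status != STATUS_OK:
            return vals[v], logscale, status, cr, diag
        # speciation event at the node: D_s = lam_s * D_left_s * D_right_s
        vals[v, 0] = 0.5 * (yl[0] + yr[0])
        vals[v, 1] = 0.5 * (yl[1] + yr[1])
        vals[v, 2] = pars[0] * yl[2] * yr[2]
        vals[v, 3] = pars[3] * yl[3] * yr[3]
        s = vals[v, 2] + vals[v, 3]
        if not (s > 0.0 and np.isfinite(s)):
            return vals[v], logscale, STATUS_NONFINITE, v, diag
        vals[v, 2] /= s
        vals[v, 3] /= s
        logscale += np.log(s)
    return vals[post_internal[-1]], logscale, STATUS_OK, -1, diag
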