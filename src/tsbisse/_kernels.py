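"""Compiled numerical kernels for the time-sliced BiSSE likelihood.

Everything here works on flat arrays (see :mod:`tsbisse.treeio` for the
layout) and is jitted with numba.  The state vector along a branch is
``y = (E0, E1, D0, D1)`` integrated in age (towards the past) with an
embedded Dormand–Prince 5(4) pair; rates are piecewise constant in age, so
the integrator is restarted exactly at every epoch boundary.

``rates`` rows are ordered ``(lam0, lam1, mu0, mu1, q01, q10)``; row k is
the epoch older than ``breakpoints[k-1]`` (row 0 = most recent epoch).
"""

import numpy as np
from numba import njit

# rates row layout
LAM0, LAM1, MU0, MU1, Q01, Q10 = 0, 1, 2, 3, 4, 5

# per-segment step budget: generous for any plausible rate set (a 105 Myr
# span at rates ~10 Myr^-1 needs a few thousand steps), but small enough
# that hopeless corners of parameter space fail fast inside optimizers
MAX_STEPS = 50_000


@njit(cache=True, inline="always")
def _rhs4(E0, E1, D0, D1, lam0, lam1, mu0, mu1, q01, q10):
    dE0 = mu0 - (lam0 + mu0 + q01) * E0 + q01 * E1 + lam0 * E0 * E0
    dE1 = mu1 - (lam1 + mu1 + q10) * E1 + q10 * E0 + lam1 * E1 * E1
    dD0 = -(lam0 + mu0 + q01) * D0 + q01 * D1 + 2.0 * lam0 * E0 * D0
    dD1 = -(lam1 + mu1 + q10) * D1 + q10 * D0 + 2.0 * lam1 * E1 * D1
    return dE0, dE1, dD0, dD1


@njit(cache=True)
def _integrate_const_scalar(E0, E1, D0, D1, t0, t1, lam0, lam1, mu0, mu1,
                            q01, q10, rtol, atol):
    """Adaptive Dormand-Prince 5(4) on scalars (no per-step allocation).

    Returns (E0, E1, D0, D1, ok).  E components are clamped to [0, 1]
    against round-off drift.
    """
    span = t1 - t0
    if span <= 0.0:
        return E0, E1, D0, D1, True
    rmax = max(lam0, lam1, mu0, mu1, q01, q10)
    h = span
    if rmax > 0.0 and 0.1 / rmax < h:
        h = 0.1 / rmax
    # step-size floor bounds the per-segment cost; it only binds at
    # extreme rate x span products, far from any plausible optimum, where
    # degraded local accuracy is preferable to an unbounded step count
    h_min = span / 1500.0
    t = t0
    nsteps = 0
    while t < t1:
        if nsteps > MAX_STEPS:
            return E0, E1, D0, D1, False
        nsteps += 1
        if t + h > t1:
            h = t1 - t
        a0, a1, a2, a3 = _rhs4(E0, E1, D0, D1, lam0, lam1, mu0, mu1, q01, q10)
        b0, b1, b2, b3 = _rhs4(
            E0 + h * 0.2 * a0, E1 + h * 0.2 * a1,
            D0 + h * 0.2 * a2, D1 + h * 0.2 * a3,
            lam0, lam1, mu0, mu1, q01, q10,
        )
        c0, c1, c2, c3 = _rhs4(
            E0 + h * (0.075 * a0 + 0.225 * b0),
            E1 + h * (0.075 * a1 + 0.225 * b1),
            D0 + h * (0.075 * a2 + 0.225 * b2),
            D1 + h * (0.075 * a3 + 0.225 * b3),
            lam0, lam1, mu0, mu1, q01, q10,
        )
        w1 = 44.0 / 45.0
        w2 = -56.0 / 15.0
        w3 = 32.0 / 9.0
        d0, d1, d2, d3 = _rhs4(
            E0 + h * (w1 * a0 + w2 * b0 + w3 * c0),
            E1 + h * (w1 * a1 + w2 * b1 + w3 * c1),
            D0 + h * (w1 * a2 + w2 * b2 + w3 * c2),
            D1 + h * (w1 * a3 + w2 * b3 + w3 * c3),
            lam0, lam1, mu0, mu1, q01, q10,
        )
        v1 = 19372.0 / 6561.0
        v2 = -25360.0 / 2187.0
        v3 = 64448.0 / 6561.0
        v4 = -212.0 / 729.0
        e0, e1, e2, e3 = _rhs4(
            E0 + h * (v1 * a0 + v2 * b0 + v3 * c0 + v4 * d0),
            E1 + h * (v1 * a1 + v2 * b1 + v3 * c1 + v4 * d1),
            D0 + h * (v1 * a2 + v2 * b2 + v3 * c2 + v4 * d2),
            D1 + h * (v1 * a3 + v2 * b3 + v3 * c3 + v4 * d3),
            lam0, lam1, mu0, mu1, q01, q10,
        )
        u1 = 9017.0 / 3168.0
        u2 = -355.0 / 33.0
        u3 = 46732.0 / 5247.0
        u4 = 49.0 / 176.0
        u5 = -5103.0 / 18656.0
        f0, f1, f2, f3 = _rhs4(
            E0 + h * (u1 * a0 + u2 * b0 + u3 * c0 + u4 * d0 + u5 * e0),
            E1 + h * (u1 * a1 + u2 * b1 + u3 * c1 + u4 * d1 + u5 * e1),
            D0 + h * (u1 * a2 + u2 * b2 + u3 * c2 + u4 * d2 + u5 * e2),
            D1 + h * (u1 * a3 + u2 * b3 + u3 * c3 + u4 * d3 + u5 * e3),
            lam0, lam1, mu0, mu1, q01, q10,
        )
        s1 = 35.0 / 384.0
        s3 = 500.0 / 1113.0
        s4 = 125.0 / 192.0
        s5 = -2187.0 / 6784.0
        s6 = 11.0 / 84.0
        nE0 = E0 + h * (s1 * a0 + s3 * c0 + s4 * d0 + s5 * e0 + s6 * f0)
        nE1 = E1 + h * (s1 * a1 + s3 * c1 + s4 * d1 + s5 * e1 + s6 * f1)
        nD0 = D0 + h * (s1 * a2 + s3 * c2 + s4 * d2 + s5 * e2 + s6 * f2)
        nD1 = D1 + h * (s1 * a3 + s3 * c3 + s4 * d3 + s5 * e3 + s6 * f3)
        g0, g1, g2, g3 = _rhs4(nE0, nE1, nD0, nD1, lam0, lam1, mu0, mu1, q01, q10)
        r1 = 71.0 / 57600.0
        r3 = -71.0 / 16695.0
        r4 = 71.0 / 1920.0
        r5 = -17253.0 / 339200.0
        r6 = 22.0 / 525.0
        r7 = -1.0 / 40.0
        err0 = h * (r1 * a0 + r3 * c0 + r4 * d0 + r5 * e0 + r6 * f0 + r7 * g0)
        err1 = h * (r1 * a1 + r3 * c1 + r4 * d1 + r5 * e1 + r6 * f1 + r7 * g1)
        err2 = h * (r1 * a2 + r3 * c2 + r4 * d2 + r5 * e2 + r6 * f2 + r7 * g2)
        err3 = h * (r1 * a3 + r3 * c3 + r4 * d3 + r5 * e3 + r6 * f3 + r7 * g3)
        # overflowing stages (huge rate x step products) are rejected by
        # shrinking the step; persistent overflow at the floor fails the
        # whole segment (the caller maps that to log-likelihood = -inf)
        if not (
            np.isfinite(nE0) and np.isfinite(nE1)
            and np.isfinite(nD0) and np.isfinite(nD1)
        ):
            if h <= h_min:
                return E0, E1, D0, D1, False
            h = h * 0.2 if h * 0.2 > h_min else h_min
            continue
        errnorm = 0.0
        sc = atol + rtol * max(abs(E0), abs(nE0))
        errnorm = max(errnorm, abs(err0) / sc)
        sc = atol + rtol * max(abs(E1), abs(nE1))
        errnorm = max(errnorm, abs(err1) / sc)
        sc = atol + rtol * max(abs(D0), abs(nD0))
        errnorm = max(errnorm, abs(err2) / sc)
        sc = atol + rtol * max(abs(D1), abs(nD1))
        errnorm = max(errnorm, abs(err3) / sc)
        if errnorm <= 1.0 or h <= h_min:
            t += h
            E0, E1, D0, D1 = nE0, nE1, nD0, nD1
            # clamp extinction probabilities against round-off drift
            if E0 < 0.0:
                E0 = 0.0
            elif E0 > 1.0:
                E0 = 1.0
            if E1 < 0.0:
                E1 = 0.0
            elif E1 > 1.0:
                E1 = 1.0
            if not (np.isfinite(D0) and np.isfinite(D1)):
                return E0, E1, D0, D1, False
        fac = 2.0
        if errnorm > 0.0:
            fac = 0.9 * errnorm ** (-0.2)
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h *= fac
        if h < h_min:
            h = h_min
    return E0, E1, D0, D1, True


@njit(cache=True)
def _rhs(y, r):
    """Array-facing BiSSE right-hand side (public ode_rhs path)."""
    d0, d1, d2, d3 = _rhs4(
        y[0], y[1], y[2], y[3], r[0], r[1], r[2], r[3], r[4], r[5]
    )
    return np.array((d0, d1, d2, d3))


@njit(cache=True)
def integrate_const(y0, t0, t1, r, rtol, atol):
    """Array-facing wrapper over the scalar integrator."""
    y = y0.copy()
    E0, E1, D0, D1, ok = _integrate_const_scalar(
        y[0], y[1], y[2], y[3], t0, t1,
        r[0], r[1], r[2], r[3], r[4], r[5], rtol, atol,
    )
    y[0] = E0
    y[1] = E1
    y[2] = D0
    y[3] = D1
    return y, ok


@njit(cache=True)
def integrate_branch(y0, age_lo, age_hi, breakpoints, rates, rtol, atol):
    """Integrate from age_lo up to age_hi, switching epochs at breakpoints.

    Returns (y, log_scale, ok): D components are rescaled so max(D) = 1 at
    the end of the branch, with the log factor returned separately.
    """
    y = y0.copy()
    ok = True
    if age_hi <= age_lo:
        return y, 0.0, True
    nbp = breakpoints.shape[0]
    t = age_lo
    for k in range(nbp + 1):
        seg_hi = age_hi
        if k < nbp and breakpoints[k] < age_hi:
            seg_hi = breakpoints[k]
        if seg_hi <= t:
            continue
        # epoch k covers ages < breakpoints[k]; pick the row for this span
        y, ok = integrate_const(y, t, seg_hi, rates[k], rtol, atol)
        if not ok:
            return y, 0.0, False
        t = seg_hi
        if t >= age_hi:
            break
    logsc = 0.0
    dmax = y[2] if y[2] > y[3] else y[3]
    if dmax > 0.0 and np.isfinite(dmax):
        y[2] /= dmax
        y[3] /= dmax
        logsc = np.log(dmax)
    return y, logsc, ok


@njit(cache=True)
def epoch_index(age, breakpoints):
    """Epoch containing ``age``; ties at a breakpoint go to the older epoch."""
    k = 0
    for j in range(breakpoints.shape[0]):
        if age >= breakpoints[j]:
            k = j + 1
    return k


@njit(cache=True)
def tree_loglik_arrays(
    n_tips,
    children,
    parent,
    age,
    tip_states,
    breakpoints,
    rates,
    f0,
    f1,
    root_mode,  # 0 = fitzjohn (state-weighted), 1 = equal, 2 = fixed prior
    prior0,
    prior1,
    condition_surv,
    rtol,
    atol,
    force_node=-1,
    force_state=-1,
):
    """Postorder pruning log-likelihood.  Returns -inf on numerical failure.

    ``force_node >= 0`` clamps that node to ``force_state`` (zeroing the
    other state's partial after the node combination) — the building block
    for marginal ancestral-state reconstruction.
    """
    N = children.shape[0]
    E = np.zeros((N, 2))
    D = np.zeros((N, 2))
    loglik_scale = 0.0
    # tip initial conditions (skeletal-tree sampling correction)
    for v in range(n_tips):
        E[v, 0] = 1.0 - f0
        E[v, 1] = 1.0 - f1
        if tip_states[v] == 0:
            D[v, 0] = f0
        else:
            D[v, 1] = f1
    y = np.zeros(4)
    for v in range(n_tips, N):
        cl = children[v, 0]
        cr = children[v, 1]
        node_age = age[v]
        # bring each child's partials up to the node
        for side in range(2):
            c = cl if side == 0 else cr
            y[0] = E[c, 0]
            y[1] = E[c, 1]
            y[2] = D[c, 0]
            y[3] = D[c, 1]
            if node_age > age[c]:
                y, lsc, ok = integrate_branch(
                    y, age[c], node_age, breakpoints, rates, rtol, atol
                )
                if not ok:
                    return -np.inf
                loglik_scale += lsc
            E[c, 0] = y[0]
            E[c, 1] = y[1]
            D[c, 0] = y[2]
            D[c, 1] = y[3]
        ep = epoch_index(node_age, breakpoints)
        D[v, 0] = rates[ep, LAM0] * D[cl, 0] * D[cr, 0]
        D[v, 1] = rates[ep, LAM1] * D[cl, 1] * D[cr, 1]
        if v == force_node:
            D[v, 1 - force_state] = 0.0
        # E at the node: children trajectories coincide up to solver error
        E[v, 0] = 0.5 * (E[cl, 0] + E[cr, 0])
        E[v, 1] = 0.5 * (E[cl, 1] + E[cr, 1])
        dmax = D[v, 0] if D[v, 0] > D[v, 1] else D[v, 1]
        if not (dmax > 0.0) or not np.isfinite(dmax):
            return -np.inf
        D[v, 0] /= dmax
        D[v, 1] /= dmax
        loglik_scale += np.log(dmax)
    root = N - 1
    d0 = D[root, 0]
    d1 = D[root, 1]
    dsum = d0 + d1
    if root_mode == 0:
        w0 = d0 / dsum
        w1 = d1 / dsum
    elif root_mode == 1:
        w0 = 0.5
        w1 = 0.5
    else:
        w0 = prior0
        w1 = prior1
    if condition_surv:
        ep = epoch_index(age[root], breakpoints)
        s0 = rates[ep, LAM0] * (1.0 - E[root, 0]) ** 2
        s1 = rates[ep, LAM1] * (1.0 - E[root, 1]) ** 2
        if s0 <= 0.0 or s1 <= 0.0:
            return -np.inf
        d0 = d0 / s0
        d1 = d1 / s1
    lik = w0 * d0 + w1 * d1
    if not (lik > 0.0) or not np.isfinite(lik):
        return -np.inf
    return np.log(lik) + loglik_scale
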