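"""Independent oracles used by the test suite.

Everything here is deliberately written without touching the package's
compiled kernels: a fixed-step classical RK4 integrator for the BiSSE
ODEs, a matrix-exponential Mk pruning likelihood, and small closed forms.
They trade speed for transparency and serve as the second route in
dual-route checks.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def bisse_rhs(y, rates):
    """(E0, E1, D0, D1) derivative under one epoch's rates (dict-like)."""
    lam0, lam1 = rates["lam0"], rates["lam1"]
    mu0, mu1 = rates["mu0"], rates["mu1"]
    q01, q10 = rates["q01"], rates["q10"]
    E0, E1, D0, D1 = y
    return np.array(
        [
            mu0 - (lam0 + mu0 + q01) * E0 + q01 * E1 + lam0 * E0 * E0,
            mu1 - (lam1 + mu1 + q10) * E1 + q10 * E0 + lam1 * E1 * E1,
            -(lam0 + mu0 + q01) * D0 + q01 * D1 + 2 * lam0 * E0 * D0,
            -(lam1 + mu1 + q10) * D1 + q10 * D0 + 2 * lam1 * E1 * D1,
        ]
    )


def rk4_integrate(y, t0, t1, rates, step=1e-3):
    """Classical fixed-step RK4 from t0 to t1 (t in age)."""
    span = t1 - t0
    n = max(1, int(np.ceil(span / step)))
    h = span / n
    for _ in range(n):
        k1 = bisse_rhs(y, rates)
        k2 = bisse_rhs(y + 0.5 * h * k1, rates)
        k3 = bisse_rhs(y + 0.5 * h * k2, rates)
        k4 = bisse_rhs(y + h * k3, rates)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def rates_dict(epoch):
    return {
        "lam0": epoch.lam0,
        "lam1": epoch.lam1,
        "mu0": epoch.mu0,
        "mu1": epoch.mu1,
        "q01": epoch.q01,
        "q10": epoch.q10,
    }


def bisse_loglik_rk4(tree, states, params, f0=1.0, f1=1.0,
                     root_mode="fitzjohn", condition_surv=True, step=1e-3):
    """Brute-force BiSSE pruning log-likelihood via fixed-step RK4.

    Mirrors the model conventions (tip sampling correction, node
    combination with the node-age epoch's speciation rate, root weighting,
    survival conditioning) with an entirely separate integration path.
    """
    bp = list(params.breakpoints)
    epochs = list(params.epochs)

    def epoch_of(age):
        k = 0
        for j, b in enumerate(bp):
            if age >= b:
                k = j + 1
        return k

    def integrate(y, a_lo, a_hi):
        cuts = [a_lo] + [b for b in bp if a_lo < b < a_hi] + [a_hi]
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            y = rk4_integrate(y, lo, hi, rates_dict(epochs[epoch_of(lo)]), step)
        return y

    N = tree.n_nodes
    vals = {}
    for v in range(tree.n_tips):
        E = np.array([1.0 - f0, 1.0 - f1])
        D = np.zeros(2)
        D[states[v]] = f0 if states[v] == 0 else f1
        vals[v] = np.concatenate([E, D])
    logsc = 0.0
    for v in range(tree.n_tips, N):
        parts = []
        for c in tree.children[v]:
            y = vals[c]
            if tree.age[v] > tree.age[c]:
                y = integrate(y.copy(), float(tree.age[c]), float(tree.age[v]))
            parts.append(y)
        ep = epochs[epoch_of(float(tree.age[v]))]
        lam = np.array([ep.lam0, ep.lam1])
        D = lam * parts[0][2:] * parts[1][2:]
        E = 0.5 * (parts[0][:2] + parts[1][:2])
        mx = D.max()
        logsc += np.log(mx)
        vals[v] = np.concatenate([E, D / mx])
    root = vals[N - 1]
    E, D = root[:2], root[2:]
    if root_mode == "fitzjohn":
        w = D / D.sum()
    else:
        w = np.array([0.5, 0.5])
    if condition_surv:
        ep = epochs[epoch_of(float(tree.age[N - 1]))]
        lam = np.array([ep.lam0, ep.lam1])
        D = D / (lam * (1 - E) ** 2)
    return float(np.log(np.sum(w * D)) + logsc)


def mk_loglik_expm(tree, states, q01, q10, root_mode="fitzjohn"):
    """Mk pruning likelihood via scipy's matrix exponential."""
    Q = np.array([[-q01, q01], [q10, -q10]])
    vals = {}
    for v in range(tree.n_tips):
        M = np.zeros(2)
        M[states[v]] = 1.0
        vals[v] = M
    for v in range(tree.n_tips, tree.n_nodes):
        part = np.ones(2)
        for c in tree.children[v]:
            P = expm(Q * float(tree.branch_length[c]))
            part = part * (P @ vals[c])
        vals[v] = part
    m = vals[tree.n_nodes - 1]
    if root_mode == "fitzjohn":
        lik = (m**2).sum() / m.sum()
    elif root_mode == "equal":
        lik = m.mean()
    else:
        raise ValueError(root_mode)
    return float(np.log(lik))


def yule_branching_cdf(t, lam, T):
    """CDF of a single non-crown branching age of a Yule tree conditioned
    on crown age T (iid order-statistic density e^{-lam t} normalized)."""
    return (1 - np.exp(-lam * t)) / (1 - np.exp(-lam * T))
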