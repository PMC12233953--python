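"""Numba-compiled per-trial log-likelihood kernels.

These mirror the pure-Python agents in :mod:`beliefbandit.agents` exactly
(the test suite asserts per-trial agreement) and exist only to make
maximum-likelihood fitting and the simulate/cross-fit identification studies
fast.  Each kernel walks a concatenated choice/reward sequence, resetting the
agent state wherever ``new_sess`` is set, and returns the log probability of
the observed choice on every trial.  Probabilities are floored at 1e-12
before the log so the objective stays finite everywhere in the box bounds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

P_FLOOR = 1e-12


@njit(cache=True)
def _logp_choice(D, prev, beta, phi, c):
    x = beta * D + phi * prev
    # numerically safe log-sigmoid of +/- x
    z = x if c == 1 else -x
    if z > -30.0:
        p = 1.0 / (1.0 + math.exp(-z))
    else:
        p = 0.0
    if p < P_FLOOR:
        p = P_FLOOR
    return math.log(p)


@njit(cache=True)
def nll_rl4p(c, r, new_sess, ap, am, beta, phi, counterfactual):
    n = c.shape[0]
    out = np.empty(n)
    q_l = 0.5
    q_r = 0.5
    prev = 0.0
    for i in range(n):
        if new_sess[i]:
            q_l = 0.5
            q_r = 0.5
            prev = 0.0
        D = q_r - q_l
        out[i] = _logp_choice(D, prev, beta, phi, c[i])
        qc = q_r if c[i] == 1 else q_l
        qu = q_l if c[i] == 1 else q_r
        delta = r[i] - qc
        alpha = ap if delta >= 0 else am
        qc = qc + alpha * delta
        if counterfactual:
            qu = qu + alpha * ((1.0 - r[i]) - qu)
        if c[i] == 1:
            q_r, q_l = qc, qu
        else:
            q_l, q_r = qc, qu
        prev = c[i]
    return out


@njit(cache=True)
def nll_rlfq(c, r, new_sess, ap, am, beta, zeta):
    n = c.shape[0]
    out = np.empty(n)
    q_l = 0.5
    q_r = 0.5
    prev = 0.0
    for i in range(n):
        if new_sess[i]:
            q_l = 0.5
            q_r = 0.5
            prev = 0.0
        D = q_r - q_l
        out[i] = _logp_choice(D, prev, beta, 0.0, c[i])
        qc = q_r if c[i] == 1 else q_l
        qu = q_l if c[i] == 1 else q_r
        delta = r[i] - qc
        alpha = ap if delta >= 0 else am
        qc = qc + alpha * delta
        qu = zeta * qu
        if c[i] == 1:
            q_r, q_l = qc, qu
        else:
            q_l, q_r = qc, qu
        prev = c[i]
    return out


@njit(cache=True)
def nll_rflr(c, r, new_sess, alpha, phi, tau):
    n = c.shape[0]
    out = np.empty(n)
    decay = math.exp(-1.0 / tau)
    D = 0.0
    prev = 0.0
    for i in range(n):
        if new_sess[i]:
            D = 0.0
            prev = 0.0
        out[i] = _logp_choice(D, prev, 1.0, phi, c[i])
        D = decay * D + alpha * r[i] * c[i]
        prev = c[i]
    return out


@njit(cache=True)
def nll_rlmeta(c, r, new_sess, ap, am0, beta, phi, zeta, anu, psi):
    n = c.shape[0]
    out = np.empty(n)
    q_l = 0.5
    q_r = 0.5
    prev = 0.0
    omega = 0.0
    am_t = am0
    for i in range(n):
        if new_sess[i]:
            q_l = 0.5
            q_r = 0.5
            prev = 0.0
            omega = 0.0
            am_t = am0
        D = q_r - q_l
        out[i] = _logp_choice(D, prev, beta, phi, c[i])
        qc = q_r if c[i] == 1 else q_l
        qu = q_l if c[i] == 1 else q_r
        delta = r[i] - qc
        nu = abs(delta) - omega
        if delta < 0:
            am_t = psi * (nu + am0) + (1.0 - psi) * am_t
            if am_t < 0.0:
                am_t = 0.0
        omega = omega + anu * nu
        alpha = ap if delta >= 0 else am_t
        qc = qc + alpha * delta
        qu = zeta * qu
        if c[i] == 1:
            q_r, q_l = qc, qu
        else:
            q_l, q_r = qc, qu
        prev = c[i]
    return out


@njit(cache=True)
def nll_pearcehall(c, r, new_sess, ap, am, beta, phi, anu0, psi, zeta):
    n = c.shape[0]
    out = np.empty(n)
    q0 = 0.5
    q_l = 0.5
    q_r = 0.5
    prev = 0.0
    alpha_nu = anu0
    for i in range(n):
        if new_sess[i]:
            q_l = 0.5
            q_r = 0.5
            prev = 0.0
            alpha_nu = anu0
        D = q_r - q_l
        out[i] = _logp_choice(D, prev, beta, phi, c[i])
        qc = q_r if c[i] == 1 else q_l
        qu = q_l if c[i] == 1 else q_r
        delta = r[i] - qc
        alpha_nu = alpha_nu + psi * (abs(delta) - alpha_nu)
        alpha = ap if delta >= 0 else am
        qc = qc + alpha_nu * alpha * delta
        qu = q0 + zeta * (qu - q0)
        if c[i] == 1:
            q_r, q_l = qc, qu
        else:
            q_l, q_r = qc, qu
        prev = c[i]
    return out


@njit(cache=True)
def nll_belief(c, r, new_sess, beta, phi, q, alpha_w, rho1, rho2, variant):
    """Belief-state family.

    variant: 0 = BIfp (D = 2b-1, no weight learning), 1 = BRLfwr (w2 fixed),
    2 = BRLfw (both weights learned), 3 = BRLwrp (same recursion as fw; the
    fitted rho1/rho2 arrive through the rho arguments).
    """
    n = c.shape[0]
    out = np.empty(n)
    b = 0.5
    prev = 0.0
    w1 = rho1
    w2 = rho2
    for i in range(n):
        if new_sess[i]:
            b = 0.5
            prev = 0.0
            w1 = rho1
            w2 = rho2
        if variant == 0:
            D = 2.0 * b - 1.0
        else:
            # Q(+1) - Q(-1) = (w1 - w2) * (2b - 1)
            D = (w1 - w2) * (2.0 * b - 1.0)
        out[i] = _logp_choice(D, prev, beta, phi, c[i])
        bc = b if c[i] == 1 else 1.0 - b
        if variant >= 1:
            qc = w1 * bc + w2 * (1.0 - bc)
            delta = r[i] - qc
            w1_new = w1 + alpha_w * delta * bc
            if variant >= 2:
                w2 = w2 + alpha_w * delta * (1.0 - bc)
            w1 = w1_new
        # forward filter step
        lik_pos = rho1 if c[i] == 1 else rho2
        lik_neg = rho1 if c[i] == -1 else rho2
        if r[i] == 0:
            lik_pos = 1.0 - lik_pos
            lik_neg = 1.0 - lik_neg
        num = b * lik_pos
        den = num + (1.0 - b) * lik_neg
        post = num / den
        b = (1.0 - q) * post + q * (1.0 - post)
        prev = c[i]
    return out
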