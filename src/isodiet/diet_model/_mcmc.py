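"""Random-walk Metropolis kernel on additive-log-ratio simplex coordinates.

The target is the marginal posterior of the diet fractions: a flat
Dirichlet(1,...,1) prior on the simplex (whose ALR-space density contributes
the log-Jacobian sum(log f)) times the Gaussian likelihood with source
values and diet-to-consumer offsets integrated out.  Proposals are
component-wise Gaussian steps, adapted multiplicatively during burn-in
toward a 0.35 acceptance rate and frozen afterwards.

Compiled with numba; the kernel is seeded internally so that a fit is a
pure function of its inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _logpost(z, q, mu, var_src, off_mean, var_off, x, var_meas, f_buf):
    K = q.shape[0]
    S = q.shape[1]
    # ALR transform: f_k = exp(z_k)/denom (k < K-1), f_{K-1} = 1/denom
    denom = 1.0
    zmax = 0.0
    for k in range(K - 1):
        if z[k] > zmax:
            zmax = z[k]
    denom = np.exp(-zmax)
    for k in range(K - 1):
        denom += np.exp(z[k] - zmax)
    logdenom = zmax + np.log(denom)
    lp = 0.0
    for k in range(K - 1):
        f_buf[k] = np.exp(z[k] - logdenom)
        lp += z[k] - logdenom
    f_buf[K - 1] = np.exp(-logdenom)
    lp += -logdenom
    ll = 0.0
    for s in range(S):
        total = 0.0
        for k in range(K):
            total += f_buf[k] * q[k, s]
        m = off_mean[s]
        v = var_meas[s] + var_off[s]
        for k in range(K):
            w = f_buf[k] * q[k, s] / total
            m += w * mu[k, s]
            v += w * w * var_src[k, s]
        r = x[s] - m
        ll += -0.5 * (np.log(2.0 * np.pi * v) + r * r / v)
    return lp + ll, ll


@njit(cache=True)
def _mh_kernel(q, mu, var_src, off_mean, var_off, x, var_meas,
               n_burn, n_iter, seed):
    np.random.seed(seed)
    K = q.shape[0]
    D = K - 1
    z = np.zeros(D)
    f_buf = np.zeros(K)
    f_prop = np.zeros(K)
    steps = np.full(D, 0.5)
    lp, ll = _logpost(z, q, mu, var_src, off_mean, var_off, x, var_meas, f_buf)

    chains = np.empty((n_iter, K))
    logliks = np.empty(n_iter)
    win_prop = np.zeros(D)
    win_acc = np.zeros(D)
    n_acc = 0
    n_prop = 0

    zp = np.empty(D)
    for it in range(n_burn + n_iter):
        burn = it < n_burn
        for d in range(D):
            for j in range(D):
                zp[j] = z[j]
            zp[d] = z[d] + steps[d] * np.random.normal()
            lp_new, ll_new = _logpost(zp, q, mu, var_src, off_mean, var_off,
                                      x, var_meas, f_prop)
            accept = np.log(np.random.random()) < lp_new - lp
            if burn:
                win_prop[d] += 1.0
                if accept:
                    win_acc[d] += 1.0
            else:
                n_prop += 1
                if accept:
                    n_acc += 1
            if accept:
                z[d] = zp[d]
                lp = lp_new
                ll = ll_new
                for k in range(K):
                    f_buf[k] = f_prop[k]
        if burn and (it + 1) % 50 == 0:
            for d in range(D):
                if win_prop[d] > 0:
                    rate = win_acc[d] / win_prop[d]
                    fac = np.exp(rate - 0.35)
                    if fac < 0.5:
                        fac = 0.5
                    if fac > 2.0:
                        fac = 2.0
                    steps[d] *= fac
                    if steps[d] < 1e-3:
                        steps[d] = 1e-3
                    if steps[d] > 10.0:
                        steps[d] = 10.0
                win_prop[d] = 0.0
                win_acc[d] = 0.0
        if not burn:
            for k in range(K):
                chains[it - n_burn, k] = f_buf[k]
            logliks[it - n_burn] = ll

    acc_rate = n_acc / n_prop if n_prop > 0 else 0.0
    return chains, logliks, acc_rate, steps


def run_chain(q: np.ndarray, mu: np.ndarray, var_src: np.ndarray,
              off_mean: np.ndarray, var_off: np.ndarray,
              x: np.ndarray, var_meas: np.ndarray,
              burn_in: int, iterations: int, seed: int):
    """Run one seeded chain; returns (fraction draws, logliks, acceptance
    rate, final step sizes)."""
    seed = int(seed) % (2**32)
    return _mh_kernel(np.ascontiguousarray(q, float),
                      np.ascontiguousarray(mu, float),
                      np.ascontiguousarray(var_src, float),
                      np.ascontiguousarray(off_mean, float),
                      np.ascontiguousarray(var_off, float),
                      np.ascontiguousarray(x, float),
                      np.ascontiguousarray(var_meas, float),
                      int(burn_in), int(iterations), seed)
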