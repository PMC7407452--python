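"""Exact Gaussian log-likelihood of a linear regression with ARMA(p, q) errors.

Harvey state-space form with r = max(p, q+1) states, scalar observation
y_t - alpha - beta * x_t = Z a_t, exact (stationary) initialization of the
state covariance, and a plain Kalman recursion. Jitted with numba because
the MCMC evaluates this tens of thousands of times per fit; agreement with
the statsmodels Kalman filter is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _arma_loglike_resid(resid: np.ndarray, phi: np.ndarray, theta: np.ndarray,
                        sigma2: float) -> float:
    p = len(phi)
    q = len(theta)
    r = max(p, q + 1)
    n = len(resid)

    T = np.zeros((r, r))
    for i in range(p):
        T[i, 0] = phi[i]
    for i in range(r - 1):
        T[i, i + 1] = 1.0

    R = np.zeros(r)
    R[0] = 1.0
    for i in range(q):
        R[i + 1] = theta[i]
    Q = sigma2 * np.outer(R, R)

    # stationary initial covariance: vec(P0) = (I - T (x) T)^{-1} vec(Q)
    m = r * r
    A = np.eye(m)
    for i in range(r):
        for j in range(r):
            for k in range(r):
                for l in range(r):
                    A[i * r + j, k * r + l] -= T[i, k] * T[j, l]
    P = np.linalg.solve(A, Q.reshape(m)).reshape((r, r))

    a = np.zeros(r)
    a_new = np.zeros(r)
    TP = np.zeros((r, r))
    P_new = np.zeros((r, r))
    K = np.zeros(r)
    ll = 0.0
    log2pi = 1.8378770664093453
    for t in range(n):
        v = resid[t] - a[0]
        F = P[0, 0]
        if F <= 0.0 or not np.isfinite(F):
            return -np.inf
        ll += -0.5 * (log2pi + np.log(F) + v * v / F)
        # TP = T P ; K = TP[:,0] / F ; a' = T a + K v
        for i in range(r):
            ti0 = T[i, 0]
            s_a = ti0 * a[0]
            for j in range(r):
                s = ti0 * P[0, j]
                if i + 1 < r:
                    s += P[i + 1, j]
                TP[i, j] = s
            if i + 1 < r:
                s_a += a[i + 1]
            K[i] = TP[i, 0] / F
            a_new[i] = s_a + K[i] * v
        # P' = TP T' - K (TP[:,0])' + Q   (since K F = TP[:,0])
        for i in range(r):
            for j in range(r):
                s = TP[i, 0] * T[j, 0]
                if j + 1 < r:
                    s += TP[i, j + 1]
                P_new[i, j] = s - K[i] * TP[j, 0] + Q[i, j]
        for i in range(r):
            a[i] = a_new[i]
            for j in range(r):
                P[i, j] = P_new[i, j]
    return ll


def arma_regression_loglike(y: np.ndarray, x: np.ndarray, alpha: float,
                            beta: float, phi: np.ndarray, theta: np.ndarray,
                            sigma2: float) -> float:
    """log p(y | alpha, beta, phi, theta, sigma2) for y = a + b x + ARMA noise."""
    resid = y - alpha - beta * x
    return float(_arma_loglike_resid(
        np.ascontiguousarray(resid, dtype=np.float64),
        np.ascontiguousarray(phi, dtype=np.float64),
        np.ascontiguousarray(theta, dtype=np.float64),
        float(sigma2)))
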