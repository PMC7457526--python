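"""Compiled inner loop for the Gaussian identity-link MM Newton iteration.

This mirrors the reference implementation in :mod:`gpgee.estimator` /
:mod:`gpgee.correlation` exactly (same moment estimators, same update,
same stopping rule); it exists because the lambda path of the simulation
harness runs tens of thousands of iterations.  A test asserts the two
routes agree.

Correlation structures are encoded as integers:

    0 independence          3 unstructured
    1 ar1 (full vector)     4 kron unstructured (x) ar1
    2 cs  (full vector)     5 kron unstructured (x) cs
                            6 kron unstructured (x) unstructured
                            7 kron independence (x) ar1
                            8 kron independence (x) cs
                            9 kron independence (x) unstructured
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


#: spec descriptor -> integer code (see module docstring)
CORR_CODES = {
    ("independence", None, None): 0,
    ("ar1", None, None): 1,
    ("cs", None, None): 2,
    ("unstructured", None, None): 3,
    ("kronecker", "unstructured", "ar1"): 4,
    ("kronecker", "unstructured", "cs"): 5,
    ("kronecker", "unstructured", "unstructured"): 6,
    ("kronecker", "independence", "ar1"): 7,
    ("kronecker", "independence", "cs"): 8,
    ("kronecker", "independence", "unstructured"): 9,
}

AR1_CLIP = 0.99
PD_FLOOR = 1.0e-6
RIDGE = 1.0e-8


@njit(cache=True)
def _repair_corr(M):
    """Rescale a moment matrix to unit diagonal; floor eigenvalues at 1e-6."""
    k = M.shape[0]
    d = np.empty(k)
    for i in range(k):
        d[i] = np.sqrt(M[i, i])
    R = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            R[i, j] = M[i, j] / (d[i] * d[j])
    for i in range(k):
        R[i, i] = 1.0
        for j in range(i):
            v = 0.5 * (R[i, j] + R[j, i])
            R[i, j] = v
            R[j, i] = v
    w = np.linalg.eigvalsh(R)
    if w[0] > 1.0e-10:
        return R
    vals, vecs = np.linalg.eigh(R)
    for i in range(k):
        if vals[i] < PD_FLOOR:
            vals[i] = PD_FLOOR
    F = (vecs * vals) @ vecs.T
    for i in range(k):
        d[i] = np.sqrt(F[i, i])
    for i in range(k):
        for j in range(k):
            R[i, j] = F[i, j] / (d[i] * d[j])
        R[i, i] = 1.0
    return R


@njit(cache=True)
def _estimate_R(e, code, J, K):
    """Moment-estimate the working correlation from residuals e (n, J, K)."""
    n = e.shape[0]
    m = J * K
    msq = 0.0
    for i in range(n):
        for j in range(J):
            for k in range(K):
                msq += e[i, j, k] * e[i, j, k]
    msq /= n * m

    R = np.eye(m)
    if code == 0:
        return R

    if code == 1 or code == 4 or code == 7:
        num = 0.0
        for i in range(n):
            for j in range(J):
                for k in range(K - 1):
                    num += e[i, j, k] * e[i, j, k + 1]
        rho = num / (n * J * (K - 1)) / msq
        if rho > AR1_CLIP:
            rho = AR1_CLIP
        if rho < -AR1_CLIP:
            rho = -AR1_CLIP
        if code == 1:
            for s in range(m):
                for t in range(m):
                    R[s, t] = rho ** abs(s - t)
            return R
        Sig = np.empty((K, K))
        for s in range(K):
            for t in range(K):
                Sig[s, t] = rho ** abs(s - t)
    elif code == 2:
        tot = 0.0
        for i in range(n):
            ssum = 0.0
            for j in range(J):
                for k in range(K):
                    ssum += e[i, j, k]
            tot += ssum * ssum
        off = (tot - msq * n * m) / (n * m * (m - 1))
        rho = off / msq
        lower = -1.0 / (m - 1) + 1e-6
        if rho < lower:
            rho = lower
        if rho > AR1_CLIP:
            rho = AR1_CLIP
        for s in range(m):
            for t in range(m):
                R[s, t] = rho
            R[s, s] = 1.0
        return R
    elif code == 5 or code == 8:
        tot = 0.0
        for i in range(n):
            for j in range(J):
                ssum = 0.0
                sq = 0.0
                for k in range(K):
                    ssum += e[i, j, k]
                    sq += e[i, j, k] * e[i, j, k]
                tot += ssum * ssum - sq
        off = tot / (n * J * K * (K - 1))
        rho = off / msq
        lower = -1.0 / (K - 1) + 1e-6
        if rho < lower:
            rho = lower
        if rho > AR1_CLIP:
            rho = AR1_CLIP
        Sig = np.full((K, K), rho)
        for s in range(K):
            Sig[s, s] = 1.0
    elif code == 3:
        M = np.zeros((m, m))
        for i in range(n):
            for s in range(J):
                for t in range(K):
                    for u in range(J):
                        for v in range(K):
                            M[s * K + t, u * K + v] += e[i, s, t] * e[i, u, v]
        M /= n
        return _repair_corr(M)
    else:  # code 6 or 9: unstructured channel factor
        M = np.zeros((K, K))
        for i in range(n):
            for j in range(J):
                for s in range(K):
                    for t in range(K):
                        M[s, t] += e[i, j, s] * e[i, j, t]
        M /= n * J
        Sig = _repair_corr(M)

    if code == 4 or code == 5 or code == 6:
        Bm = np.zeros((J, J))
        for i in range(n):
            for k in range(K):
                for j in range(J):
                    for l in range(J):
                        Bm[j, l] += e[i, j, k] * e[i, l, k]
        Bm /= n * K
        B = _repair_corr(Bm)
    else:
        B = np.eye(J)

    for j in range(J):
        for l in range(J):
            for s in range(K):
                for t in range(K):
                    R[j * K + s, l * K + t] = B[j, l] * Sig[s, t]
    return R


@njit(cache=True)
def mm_fit_core(X, y, Gmat, lam, a, eps, tol, max_iter, code, J, K, beta0):
    """Run the MM Newton iteration; returns (beta, iters, converged, status).

    status 0 = normal exit, 1 = non-finite update (divergence).
    """
    n, m, p = X.shape
    Xf = np.ascontiguousarray(X.reshape(n * m, p))
    XfT = np.ascontiguousarray(Xf.T)
    d = Gmat.shape[0]
    beta = beta0.copy()
    H = XfT @ Xf
    RXf = Xf
    converged = False
    it_count = 0
    for it in range(1, max_iter + 1):
        it_count = it
        resid = y - (Xf @ beta).reshape(n, m)
        if code != 0:
            e3 = resid.reshape(n, J, K)
            R = _estimate_R(e3, code, J, K)
            Rinv = np.linalg.inv(R)
            RX = np.empty_like(X)
            for i in range(n):
                RX[i] = Rinv @ X[i]
            RXf = RX.reshape(n * m, p)
            H = XfT @ RXf
        S = resid.reshape(n * m) @ RXf
        absb = np.abs(beta)
        norms = Gmat @ absb
        rates = np.empty(d)
        for g in range(d):
            th = norms[g]
            if th <= lam:
                rates[g] = lam
            else:
                v = (a * lam - th) / (a - 1.0)
                rates[g] = v if v > 0.0 else 0.0
        E = (rates @ Gmat) / (eps + absb)
        M = H.copy()
        for j in range(p):
            M[j, j] += n * E[j] + RIDGE
        step = np.linalg.solve(M, S - n * E * beta)
        delta = 0.0
        finite = True
        for j in range(p):
            b = beta[j] + step[j]
            if not np.isfinite(b):
                finite = False
            delta += abs(b - beta[j])
            beta[j] = b
        if not finite:
            return beta, it_count, False, 1
        if delta < tol:
            converged = True
            break
    return beta, it_count, converged, 0
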