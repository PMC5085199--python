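"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as direct summation / explicit normal
equations / exhaustive enumeration, deliberately sharing no code with
the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math
from itertools import permutations


def dl_oracle(y, v):
    """Direct-summation fixed + DerSimonian-Laird pooling.

    Returns a dict with every intermediate: fixed weights, fixed pooled
    mean, Q, C, tau2, random weights, random pooled mean and SE.
    """
    k = len(y)
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    y_fixed = sum(wi * yi for wi, yi in zip(w, y)) / sw
    Q = sum(wi * (yi - y_fixed) ** 2 for wi, yi in zip(w, y))
    C = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (Q - (k - 1)) / C) if (k > 1 and C > 0) else 0.0
    ws = [1.0 / (vi + tau2) for vi in v]
    sws = sum(ws)
    y_random = sum(wi * yi for wi, yi in zip(ws, y)) / sws
    return {
        "y_fixed": y_fixed, "se_fixed": math.sqrt(1.0 / sw), "Q": Q, "C": C,
        "tau2": tau2, "y_random": y_random, "se_random": math.sqrt(1.0 / sws),
        "weights_fixed": [wi / sw for wi in w],
        "weights_random": [wi / sws for wi in ws],
    }


def ols_two_param_oracle(x, z):
    """Closed-form least squares of z on (1, x): intercept, slope, SEs, t."""
    n = len(x)
    xbar = sum(x) / n
    zbar = sum(z) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxz = sum((xi - xbar) * (zi - zbar) for xi, zi in zip(x, z))
    slope = sxz / sxx
    intercept = zbar - slope * xbar
    resid = [zi - intercept - slope * xi for xi, zi in zip(x, z)]
    s2 = sum(r * r for r in resid) / (n - 2)
    se_intercept = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    se_slope = math.sqrt(s2 / sxx)
    return {"intercept": intercept, "slope": slope,
            "se_intercept": se_intercept, "se_slope": se_slope,
            "t_intercept": intercept / se_intercept}


def kendall_score_oracle(u, w):
    """Pairwise-loop Kendall score (concordant minus discordant)."""
    T = 0
    n = len(u)
    for i in range(n):
        for j in range(i + 1, n):
            du = u[j] - u[i]
            dw = w[j] - w[i]
            if du * dw > 0:
                T += 1
            elif du * dw < 0:
                T -= 1
    return T


def begg_exact_p_oracle(u, v):
    """Exact two-sided permutation p for the Kendall score of u vs v."""
    T_obs = abs(kendall_score_oracle(u, v))
    n = len(u)
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        total += 1
        if abs(kendall_score_oracle(u, [v[i] for i in perm])) >= T_obs:
            hits += 1
    return hits / total


def wls_oracle(y, v, X, tau2):
    """Weighted LS at fixed tau2 by explicit normal equations (p <= 3)."""
    k = len(y)
    p = len(X[0])
    w = [1.0 / (vi + tau2) for vi in v]
    # form X'WX and X'Wy
    A = [[sum(w[i] * X[i][r] * X[i][c] for i in range(k)) for c in range(p)]
         for r in range(p)]
    b = [sum(w[i] * X[i][r] * y[i] for i in range(k)) for r in range(p)]
    return _solve(A, b)


def _solve(A, b):
    """Gaussian elimination with partial pivoting (tiny systems only)."""
    n = len(b)
    M = [row[:] + [bi] for row, bi in zip(A, b)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(M[r][col]))
        M[col], M[piv] = M[piv], M[col]
        for r in range(n):
            if r != col:
                f = M[r][col] / M[col][col]
                for c in range(col, n + 1):
                    M[r][c] -= f * M[col][c]
    return [M[i][n] / M[i][i] for i in range(n)]


def reml_loglik_oracle(tau2, y, v, X):
    """Restricted log-likelihood by explicit formula (constants dropped).

    -2 ll = sum log(v_i + tau2) + log det(X' W X) + r' W r
    """
    k = len(y)
    p = len(X[0])
    w = [1.0 / (vi + tau2) for vi in v]
    A = [[sum(w[i] * X[i][r] * X[i][c] for i in range(k)) for c in range(p)]
         for r in range(p)]
    beta = _solve(A, [sum(w[i] * X[i][r] * y[i] for i in range(k)) for r in range(p)])
    r = [y[i] - sum(X[i][c] * beta[c] for c in range(p)) for i in range(k)]
    return -0.5 * (sum(math.log(vi + tau2) for vi in v)
                   + math.log(_det(A))
                   + sum(w[i] * r[i] * r[i] for i in range(k)))


def _det(A):
    n = len(A)
    M = [row[:] for row in A]
    det = 1.0
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(M[r][col]))
        if piv != col:
            M[col], M[piv] = M[piv], M[col]
            det = -det
        det *= M[col][col]
        for r in range(col + 1, n):
            f = M[r][col] / M[col][col]
            for c in range(col, n):
                M[r][c] -= f * M[col][c]
    return det


def reml_grid_oracle(y, v, X, tau2_max=5.0, step=1e-3):
    """Best tau2 on a dense grid by the oracle restricted likelihood."""
    best_t, best_ll = 0.0, reml_loglik_oracle(0.0, y, v, X)
    t = step
    while t <= tau2_max:
        ll = reml_loglik_oracle(t, y, v, X)
        if ll > best_ll:
            best_t, best_ll = t, ll
        t += step
    return best_t, best_ll


def trapezoid_auc_oracle(fn, n=200001):
    """Dense trapezoid integral of fn over (0, 1), endpoints excluded."""
    h = 1.0 / (n + 1)
    xs = [h * (i + 1) for i in range(n)]
    ys = [fn(x) for x in xs]
    # endpoints contribute fn(0)=0-ish and fn(1)=1-ish; use limits 0 and 1
    total = 0.5 * (0.0 + ys[0]) * h + 0.5 * (ys[-1] + 1.0) * h
    for i in range(n - 1):
        total += 0.5 * (ys[i] + ys[i + 1]) * h
    return total
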