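"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles (explicit loops, naive
formulas, characteristic polynomials) and deliberately shares no code path
with the implementation under test.
"""

import math

import numpy as np


def pearson_brute(x, y):
    """Pearson correlation by the textbook formula, with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n)))
    dy = math.sqrt(sum((y[i] - my) ** 2 for i in range(n)))
    return num / (dx * dy)


def mean_cor_brute(Xk, Xl):
    """Mean over columns of the per-column Pearson correlation."""
    p = Xk.shape[1]
    return sum(pearson_brute(Xk[:, j], Xl[:, j]) for j in range(p)) / p


def rv_brute(Xk, Xl):
    """Frobenius inner product over the product of Frobenius norms."""
    num = sum(
        Xk[i, j] * Xl[i, j] for i in range(Xk.shape[0]) for j in range(Xk.shape[1])
    )
    nk = math.sqrt(sum(v * v for v in Xk.ravel()))
    nl = math.sqrt(sum(v * v for v in Xl.ravel()))
    return num / (nk * nl)


def eigvals_brute(M):
    """Eigenvalues via the roots of the characteristic polynomial, descending.

    Independent of the symmetric eigensolver route used by the package.
    """
    coeffs = np.poly(np.asarray(M, dtype=float))
    roots = np.roots(coeffs)
    return np.sort(roots.real)[::-1]


def quantile_brute(values, prob):
    """Linear interpolation of order statistics (the 'type 7' rule)."""
    v = sorted(values)
    n = len(v)
    h = (n - 1) * prob
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def holm_brute(pvalues):
    """Literal step-down Holm adjustment with explicit bookkeeping."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(indexed):
        candidate = min(1.0, (m - rank) * pvalues[idx])
        running = max(running, candidate)
        adjusted[idx] = running
    return adjusted


def morans_i_brute(values, coords, lower, upper, include_zero=False):
    """Moran's I with an explicit weight matrix and ordered double loop.

    w[h][i] = 1 when lower < d(h, i) <= upper (or d == 0 <= upper when
    ``include_zero``); I = (n / W) * sum_{h != i} w z_h z_i / sum z^2.
    """
    n = len(values)
    mean = sum(values) / n
    z = [v - mean for v in values]
    W = 0.0
    num = 0.0
    for h in range(n):
        for i in range(n):
            if h == i:
                continue
            d = math.dist(coords[h], coords[i])
            inside = lower < d <= upper or (include_zero and d == 0.0 <= upper)
            if inside:
                W += 1.0
                num += z[h] * z[i]
    den = sum(v * v for v in z)
    return (n / W) * num / den


def project_rows_brute(X, V):
    """Row projection X @ V with explicit loops."""
    n, p = X.shape
    m = V.shape[1]
    out = np.zeros((n, m))
    for i in range(n):
        for a in range(m):
            out[i, a] = sum(X[i, j] * V[j, a] for j in range(p))
    return out
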