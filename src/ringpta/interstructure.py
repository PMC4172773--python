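"""Inter-table vectorial correlation, its eigen-analysis, and table weights.

The K tables of a standardized stack are compared pairwise by a scalar
vectorial correlation, producing a symmetric K x K matrix whose non-centered
eigen-analysis yields (i) a typology of the tables (scores on the leading
components) and (ii) the nonnegative weights used to build the compromise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ringpta.datacube import TableStack
from ringpta.preprocess import check_standardized

_SYM_TOL = 1e-10


class InterstructureError(ValueError):
    pass


@dataclass
class InterstructureResult:
    """Inter-table matrix plus the outputs of its eigen-analysis.

    ``table_scores[:, m]`` are the coordinates of the K tables on component
    m, scaled by the square root of the eigenvalue; ``weights`` is the
    sign-fixed, nonnegative, sum-to-one first eigenvector used for the
    compromise.
    """

    r_matrix: np.ndarray
    method: str
    table_keys: list
    eigenvalues: np.ndarray | None = None
    table_scores: np.ndarray | None = None
    weights: np.ndarray | None = None
    inertia_pct: np.ndarray | None = None

    @property
    def n_tables(self) -> int:
        return self.r_matrix.shape[0]


def _as_standardized_pair(Xk, Xl):
    Xk = np.asarray(Xk, dtype=float)
    Xl = np.asarray(Xl, dtype=float)
    if Xk.shape != Xl.shape:
        raise InterstructureError(f"shape mismatch: {Xk.shape} vs {Xl.shape}")
    if Xk.ndim != 2:
        raise InterstructureError("tables must be 2-d")
    for name, X in (("first", Xk), ("second", Xl)):
        mu = np.abs(X.mean(axis=0)).max()
        sd0 = X.std(axis=0, ddof=0)
        sd1 = X.std(axis=0, ddof=1) if X.shape[0] > 1 else sd0
        off = min(np.abs(sd0 - 1.0).max(), np.abs(sd1 - 1.0).max())
        if mu > 1e-6 or off > 1e-6:
            raise InterstructureError(
                f"{name} table is not standardized (|mean|max={mu:.2e})"
            )
    return Xk, Xl


def vectorial_correlation(Xk, Xl, method: str = "mean_cor") -> float:
    """Scalar similarity in [-1, 1] between two same-shaped standardized tables.

    ``"mean_cor"`` is the arithmetic mean over descriptors of the per-column
    Pearson correlation between the two tables; ``"rv"`` is the Frobenius
    inner product normalized by the two Frobenius norms.
    """
    Xk, Xl = _as_standardized_pair(Xk, Xl)
    if method == "mean_cor":
        num = np.einsum("ij,ij->j", Xk, Xl)
        den = np.sqrt(
            np.einsum("ij,ij->j", Xk, Xk) * np.einsum("ij,ij->j", Xl, Xl)
        )
        r = float(np.mean(num / den))
    elif method == "rv":
        r = float(
            np.sum(Xk * Xl)
            / (np.linalg.norm(Xk) * np.linalg.norm(Xl))
        )
    else:
        raise InterstructureError(f"unknown method {method!r}")
    return float(np.clip(r, -1.0, 1.0))


def interstructure_matrix(
    stack: TableStack, method: str = "mean_cor"
) -> InterstructureResult:
    """Fill the symmetric K x K inter-table matrix (one pass per unordered pair)."""
    check_standardized(stack)
    K = stack.n_tables
    if K < 2:
        raise InterstructureError(f"need at least 2 tables, got {K}")
    R = np.eye(K)
    for k in range(K):
        for l in range(k + 1, K):
            R[k, l] = R[l, k] = vectorial_correlation(
                stack.tables[k], stack.tables[l], method=method
            )
    return InterstructureResult(
        r_matrix=R, method=method, table_keys=list(stack.table_keys)
    )


def interstructure_eigen(
    result: InterstructureResult, sign_policy: str = "majority"
) -> InterstructureResult:
    """Non-centered eigen-analysis of the inter-table matrix.

    Completes ``result`` in place with eigenvalues (descending), per-component
    inertia percentages, sqrt-eigenvalue-scaled table scores, and compromise
    weights derived from the first eigenvector: sign fixed so the majority of
    entries is positive (ties resolved by forcing the first entry
    nonnegative), negative entries floored at zero with a warning, then
    renormalized to sum one.
    """
    R = np.asarray(result.r_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InterstructureError(f"r_matrix must be square, got {R.shape}")
    asym = np.abs(R - R.T).max()
    if asym > _SYM_TOL:
        raise InterstructureError(f"r_matrix asymmetric beyond tolerance ({asym:.2e})")
    if sign_policy != "majority":
        raise InterstructureError(f"unknown sign policy {sign_policy!r}")

    evals, evecs = np.linalg.eigh((R + R.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    for m in range(evecs.shape[1]):
        v = evecs[:, m]
        pos, neg = int((v > 0).sum()), int((v < 0).sum())
        flip = neg > pos
        if neg == pos and v.any():
            flip = v[np.flatnonzero(v)[0]] < 0  # tie: first nonzero entry nonnegative
        if flip:
            evecs[:, m] = -v

    total = evals.sum()
    result.eigenvalues = evals
    result.inertia_pct = 100.0 * evals / total
    result.table_scores = evecs * np.sqrt(np.clip(evals, 0.0, None))

    w = evecs[:, 0].copy()
    if (w < 0).any():
        bad = [result.table_keys[i] for i in np.flatnonzero(w < 0)]
        warnings.warn(
            f"first-eigenvector entries negative for tables {bad[:10]}; "
            "floored at 0 for the compromise weights",
            stacklevel=2,
        )
        w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        raise InterstructureError("degenerate first eigenvector: no positive entries")
    result.weights = w / w.sum()
    return result
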