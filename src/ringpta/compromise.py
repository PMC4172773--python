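"""Weighted compromise table and its PCA.

The compromise is the weights-weighted sum of the standardized tables (the
weights sum to one, so it is a weighted mean) and captures the structure
common to the whole stack.  Its PCA yields the inertia split, variable
loadings (variable-axis correlations for the correlation circle) and row
scores (tree scores in the BY_YEAR orientation, date scores in BY_TREE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ringpta.datacube import TableStack
from ringpta.interstructure import InterstructureResult
from ringpta.preprocess import check_standardized


class CompromiseError(ValueError):
    pass


@dataclass
class CompromiseResult:
    """Compromise table plus its PCA outputs.

    ``axes`` holds the unit variable axes (right singular vectors, p x m) and
    ``row_axes`` the unit row axes (left singular vectors, rows x m); both are
    kept because the intrastructure projects supplementary tables onto them.
    ``row_scores = row_axes * singular_values`` are principal coordinates,
    ``variable_loadings`` are correlations between compromise columns and
    row-score axes.
    """

    table: np.ndarray
    weights_used: np.ndarray
    row_keys: list
    col_names: list
    pca_eigenvalues: np.ndarray | None = None
    inertia_pct: np.ndarray | None = None
    variable_loadings: np.ndarray | None = None
    row_scores: np.ndarray | None = None
    singular_values: np.ndarray | None = None
    axes: np.ndarray | None = None
    row_axes: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return 0 if self.singular_values is None else self.singular_values.size

    def col_coords(self) -> np.ndarray:
        """Column principal coordinates in the decomposition's native scaling.

        Equal to ``table.T @ row_axes`` (= axes * singular values); the anchor
        reproduced when a table identical to the compromise is projected as a
        supplementary element.
        """
        return self.axes * self.singular_values


def build_compromise(
    stack: TableStack, inter: InterstructureResult
) -> CompromiseResult:
    """Weighted sum of the standardized tables using the interstructure weights."""
    check_standardized(stack)
    if inter.weights is None:
        raise CompromiseError("interstructure eigen-analysis not run: no weights")
    w = np.asarray(inter.weights, dtype=float)
    if w.size != stack.n_tables:
        raise CompromiseError(
            f"{w.size} weights for {stack.n_tables} tables"
        )
    table = np.tensordot(w, np.stack(stack.tables), axes=1)
    return CompromiseResult(
        table=table,
        weights_used=w,
        row_keys=list(stack.row_keys),
        col_names=list(stack.col_names),
    )


def compromise_pca(
    result: CompromiseResult,
    center: bool = False,
    rescale_columns: bool = False,
    rank_tol: float = 1e-12,
) -> CompromiseResult:
    """PCA of the compromise table via SVD.

    By default the table is not re-centered: a weighted mean of column-centered
    tables is already column-centered, which is verified at run time (a warning
    is emitted and ``center=True`` honoured otherwise).  ``rescale_columns``
    optionally re-normalizes compromise columns to unit variance first.

    Axis signs follow a fixed rule: each axis is flipped so the variable with
    the largest-magnitude loading loads positively.
    """
    X = np.asarray(result.table, dtype=float)
    if not np.any(X):
        raise CompromiseError("degenerate all-zero compromise")
    col_means = X.mean(axis=0)
    if np.abs(col_means).max() > 1e-8:
        if not center:
            warnings.warn(
                "compromise columns not centered "
                f"(|mean|max={np.abs(col_means).max():.2e}); consider center=True",
                stacklevel=2,
            )
    if center:
        X = X - col_means
    if rescale_columns:
        sd = X.std(axis=0, ddof=0)
        if (sd <= rank_tol).any():
            raise CompromiseError("cannot rescale: constant compromise column")
        X = X / sd

    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > rank_tol * s[0]
    U, s, V = U[:, keep], s[keep], Vt[keep].T

    eigenvalues = s**2 / n  # uniform row weights 1/n
    inertia = 100.0 * eigenvalues / eigenvalues.sum()
    scores = U * s

    loadings = _correlation_loadings(X, scores)
    for m in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, m])))
        if loadings[j, m] < 0:
            loadings[:, m] *= -1.0
            U[:, m] *= -1.0
            V[:, m] *= -1.0
            scores[:, m] *= -1.0

    result.pca_eigenvalues = eigenvalues
    result.inertia_pct = inertia
    result.variable_loadings = loadings
    result.row_scores = scores
    result.singular_values = s
    result.axes = V
    result.row_axes = U
    return result


def _correlation_loadings(X: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with each score axis."""
    Xc = X - X.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    num = Xc.T @ Sc
    den = np.outer(
        np.sqrt(np.einsum("ij,ij->j", Xc, Xc)),
        np.sqrt(np.einsum("ij,ij->j", Sc, Sc)),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        L = num / den
    return np.clip(np.nan_to_num(L), -1.0, 1.0)
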