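"""Projection of the original tables onto the compromise axes.

Each table of the stack is projected as a supplementary element onto the
compromise PCA: rows onto the unit variable axes and descriptors onto the
unit row axes.  A per-group quantile envelope on the first axis then flags
the rows that escape the structure encapsulated in the compromise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ringpta.compromise import CompromiseResult
from ringpta.datacube import TableStack
from ringpta.preprocess import check_standardized


class IntrastructureError(ValueError):
    pass


@dataclass
class IntrastructureResult:
    """Per-table projections and envelope-outlier bookkeeping.

    ``row_coords`` is (K, rows, m), ``var_coords`` (K, p, m).  After
    :func:`envelope_outliers`, ``envelope`` holds (lower, upper) bounds per
    group -- per table when ``over="rows"``, per shared row when
    ``over="tables"`` -- ``outlier_flags`` is boolean (K, rows),
    ``outlier_counts`` its column sums (per shared row) and
    ``table_outlier_counts`` its row sums (per table).
    """

    row_coords: np.ndarray
    var_coords: np.ndarray
    table_keys: list
    row_keys: list
    col_names: list
    envelope: np.ndarray | None = None
    outlier_flags: np.ndarray | None = None
    outlier_counts: np.ndarray | None = None
    table_outlier_counts: np.ndarray | None = None
    probs: tuple | None = None
    axis: int | None = None
    over: str | None = None


def project_tables(
    stack: TableStack, comp: CompromiseResult, m: int | None = None
) -> IntrastructureResult:
    """Project every table of the stack onto the compromise PCA axes.

    ``row_coords[k] = X_k @ V`` with V the unit variable axes, and
    ``var_coords[k] = X_k.T @ U`` with U the unit row axes, so that a table
    equal to the compromise reproduces the compromise's own row scores and
    column coordinates exactly.
    """
    check_standardized(stack)
    if comp.axes is None:
        raise IntrastructureError("compromise PCA not run")
    avail = comp.n_axes
    if m is None:
        m = avail
    if m > avail:
        raise IntrastructureError(f"requested {m} axes but only {avail} available")
    V = comp.axes[:, :m]
    U = comp.row_axes[:, :m]
    row_coords = np.stack([X @ V for X in stack.tables])
    var_coords = np.stack([X.T @ U for X in stack.tables])
    return IntrastructureResult(
        row_coords=row_coords,
        var_coords=var_coords,
        table_keys=list(stack.table_keys),
        row_keys=list(stack.row_keys),
        col_names=list(stack.col_names),
    )


def envelope_outliers(
    result: IntrastructureResult,
    probs: tuple = (0.025, 0.975),
    axis: int = 1,
    over: str = "rows",
) -> IntrastructureResult:
    """Flag rows strictly outside the empirical quantile envelope on one axis.

    Parameters
    ----------
    probs : (low, high)
        Quantile probabilities of the envelope bounds.
    axis : int
        1-based compromise axis to use (default: first axis).
    over : str
        ``"rows"`` computes the envelope within each table, over its rows
        (per-year envelopes over trees in the BY_YEAR orientation);
        ``"tables"`` computes it per shared row, across the K tables
        (per-year envelopes over trees in the BY_TREE orientation, where
        trees are tables and rows are years).

    Quantiles use linear interpolation of order statistics (type 7);
    "outside" is strict, so a collapsed envelope flags nothing.
    """
    lo, hi = probs
    if not (0.0 <= lo < hi <= 1.0):
        raise IntrastructureError(f"invalid envelope probabilities {probs}")
    if axis < 1 or axis > result.row_coords.shape[2]:
        raise IntrastructureError(
            f"axis {axis} out of range 1..{result.row_coords.shape[2]}"
        )
    if over not in ("rows", "tables"):
        raise IntrastructureError(f"unknown envelope aggregation {over!r}")
    coords = result.row_coords[:, :, axis - 1]  # (K, rows)
    K, nrows = coords.shape
    group_size = nrows if over == "rows" else K
    if group_size < 3:
        raise IntrastructureError(
            f"need at least 3 values per envelope group, got {group_size}"
        )

    if over == "rows":
        bounds = np.quantile(coords, [lo, hi], axis=1, method="linear").T  # (K, 2)
        lower, upper = bounds[:, :1], bounds[:, 1:]  # broadcast over rows
    else:
        bounds = np.quantile(coords, [lo, hi], axis=0, method="linear").T  # (rows, 2)
        lower, upper = bounds[:, 0][None, :], bounds[:, 1][None, :]

    flags = (coords < lower) | (coords > upper)
    result.envelope = bounds
    result.outlier_flags = flags
    result.outlier_counts = flags.sum(axis=0)
    result.table_outlier_counts = flags.sum(axis=1)
    result.probs = (float(lo), float(hi))
    result.axis = int(axis)
    result.over = over
    return result
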