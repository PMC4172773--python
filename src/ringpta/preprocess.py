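"""Per-table column standardization preceding all PTA computation.

Each column of each table is centered and scaled independently, so the
inter-table comparison sees *structures* (correlation patterns) rather than
levels or units.  The default scale uses the population (1/n) standard
deviation; this is the convention under which the mean-of-correlations
inter-table coefficient reduces to a plain average of Pearson correlations.
"""

from __future__ import annotations

import warnings

import numpy as np

from ringpta.datacube import TableStack

#: absolute tolerance for the "column is constant" check
_CONST_TOL = 1e-12


class StandardizationError(ValueError):
    pass


def standardize_stack(
    stack: TableStack,
    ddof: int = 0,
    constant_policy: str = "fail",
) -> TableStack:
    """Center and scale every column of every table to mean 0, sd 1.

    Parameters
    ----------
    stack : TableStack
        Unstandardized stack.
    ddof : int
        Delta degrees of freedom of the scale: 0 (population, default) or 1.
    constant_policy : str
        ``"fail"`` raises on any zero-variance column; ``"drop-constant"``
        removes the offending columns from *every* table with a warning so
        the stack keeps a common column set.

    Returns
    -------
    TableStack
        New stack with ``standardized=True``; the input is not modified.
    """
    if stack.standardized:
        raise StandardizationError("stack is already standardized")
    if ddof not in (0, 1):
        raise StandardizationError(f"ddof must be 0 or 1, got {ddof}")
    if constant_policy not in ("fail", "drop-constant"):
        raise StandardizationError(f"unknown constant policy {constant_policy!r}")

    constant_cols: set[int] = set()
    for key, table in zip(stack.table_keys, stack.tables):
        sd = table.std(axis=0, ddof=ddof)
        flat = np.flatnonzero(sd <= _CONST_TOL)
        if flat.size and constant_policy == "fail":
            names = [stack.col_names[j] for j in flat]
            raise StandardizationError(
                f"constant column(s) {names} in table {key!r} "
                "(policy 'fail'; use 'drop-constant' to remove them stack-wide)"
            )
        constant_cols.update(flat.tolist())

    keep = [j for j in range(len(stack.col_names)) if j not in constant_cols]
    if constant_cols:
        dropped = [stack.col_names[j] for j in sorted(constant_cols)]
        warnings.warn(
            f"dropping constant column(s) {dropped} from all {stack.n_tables} tables",
            stacklevel=2,
        )
        if not keep:
            raise StandardizationError("all columns constant; nothing left to analyze")

    tables = []
    for table in stack.tables:
        sub = table[:, keep]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=ddof)
        tables.append((sub - mu) / sd)

    return TableStack(
        mode=stack.mode,
        tables=tables,
        table_keys=list(stack.table_keys),
        row_keys=list(stack.row_keys),
        col_names=[stack.col_names[j] for j in keep],
        standardized=True,
        coords=stack.coords,
    )


def check_standardized(stack: TableStack, tol: float = 1e-8) -> None:
    """Raise unless every column of every table has mean ~0 and norm-based sd ~1.

    The check accepts both the 1/n and 1/(n-1) scale conventions.
    """
    if not stack.standardized:
        raise StandardizationError("stack not marked standardized")
    nrow = stack.table_shape[0]
    for key, table in zip(stack.table_keys, stack.tables):
        mu = table.mean(axis=0)
        if np.abs(mu).max() > tol:
            raise StandardizationError(f"table {key!r} has non-centered columns")
        sd0 = table.std(axis=0, ddof=0)
        sd1 = table.std(axis=0, ddof=1) if nrow > 1 else sd0
        if min(np.abs(sd0 - 1.0).max(), np.abs(sd1 - 1.0).max()) > tol:
            raise StandardizationError(f"table {key!r} has non-unit-scale columns")
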