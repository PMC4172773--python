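"""Moran's I correlogram with permutation inference and Holm correction.

Distance classes partition the unordered point pairs; per class, Moran's I
is computed with binary within-class weights, its permutation null built
from one shared stream of value shuffles, and class-wise p-values are
corrected by Holm's step-down rule for a global significance statement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

#: distance classes with fewer pairs than this are flagged unreliable
MIN_PAIRS_RELIABLE = 20


class SpatialError(ValueError):
    pass


@dataclass
class DistanceClasses:
    """Partition of the n(n-1)/2 point pairs into distance bins.

    ``pair_indices[c]`` is an integer array of shape (n_pairs_c, 2) holding
    the point indices of every pair in class c.
    """

    breaks: np.ndarray
    centers: np.ndarray
    n_pairs: np.ndarray
    pair_indices: list
    unreliable: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.pair_indices)


@dataclass
class CorrelogramResult:
    class_breaks: np.ndarray
    class_centers: np.ndarray
    n_pairs: np.ndarray
    morans_i: np.ndarray
    expected_i: float
    perm_pvalues: np.ndarray
    holm_pvalues: np.ndarray
    globally_significant: bool
    alpha: float
    n_permutations: int
    seed: int | None
    unreliable: np.ndarray


def distance_classes(
    coords, n_classes: int | None = None, breaks=None
) -> DistanceClasses:
    """Bin all unordered point pairs by Euclidean distance.

    Default bins are equal-width from 0 to the maximum inter-point distance,
    their count chosen by Sturges' rule on the number of pairs; explicit
    ``breaks`` (ascending edges, first edge <= 0 allowed) override both.
    Each pair lands in exactly one class: bins are left-open/right-closed
    except the first, which also absorbs zero distances.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise SpatialError(f"coords must be (n, 2), got {coords.shape}")
    n = coords.shape[0]
    if n < 3:
        raise SpatialError(f"need at least 3 points, got {n}")
    d = pdist(coords)
    dmax = d.max()
    if dmax <= 0:
        raise SpatialError("all points coincident")

    if breaks is not None:
        breaks = np.asarray(breaks, dtype=float)
        if breaks.ndim != 1 or breaks.size < 2 or np.any(np.diff(breaks) <= 0):
            raise SpatialError("breaks must be ascending with at least 2 edges")
        if dmax > breaks[-1]:
            raise SpatialError(
                f"maximum distance {dmax:.3f} exceeds last break {breaks[-1]:.3f}"
            )
    else:
        n_pairs_total = d.size
        if n_classes is None:
            n_classes = int(np.ceil(np.log2(n_pairs_total))) + 1
        if n_classes < 1:
            raise SpatialError("n_classes must be >= 1")
        breaks = np.linspace(0.0, dmax, n_classes + 1)

    ncl = breaks.size - 1
    # left-open/right-closed; clip sends d <= breaks[0] (incl. zeros) to bin 0
    idx = np.clip(np.searchsorted(breaks[1:], d, side="left"), 0, ncl - 1)

    iu, ju = np.triu_indices(n, k=1)
    pair_indices = []
    n_pairs = np.zeros(ncl, dtype=int)
    for c in range(ncl):
        sel = idx == c
        pair_indices.append(np.column_stack([iu[sel], ju[sel]]))
        n_pairs[c] = int(sel.sum())
    centers = (breaks[:-1] + breaks[1:]) / 2.0
    return DistanceClasses(
        breaks=breaks,
        centers=centers,
        n_pairs=n_pairs,
        pair_indices=pair_indices,
        unreliable=n_pairs < MIN_PAIRS_RELIABLE,
    )


def _pair_sums(z: np.ndarray, classes: DistanceClasses) -> np.ndarray:
    """Sum of z_h * z_i over the pairs of every class."""
    return np.array(
        [
            float(z[p[:, 0]] @ z[p[:, 1]]) if p.size else np.nan
            for p in classes.pair_indices
        ]
    )


def morans_i(values, classes: DistanceClasses, class_index: int) -> float:
    """Moran's I for one distance class with binary within-class weights.

    I(d) = (n / W) * sum_{h != i} w_hi z_h z_i / sum_i z_i^2 with z the
    centered values and W the sum of weights; with symmetric binary weights
    this reduces to (n / n_pairs) * sum_pairs z_h z_i / sum z^2.
    """
    values = np.asarray(values, dtype=float).ravel()
    z = values - values.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise SpatialError("values have zero variance")
    pairs = classes.pair_indices[class_index]
    if pairs.shape[0] == 0:
        raise SpatialError(f"distance class {class_index} holds no pairs")
    n = values.size
    s = float(z[pairs[:, 0]] @ z[pairs[:, 1]])
    return n * s / (pairs.shape[0] * denom)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order.

    Sort ascending; adj_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)).
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise SpatialError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise SpatialError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def correlogram(
    values,
    coords,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    n_classes: int | None = None,
    breaks=None,
    alternative: str = "two-sided",
) -> CorrelogramResult:
    """Permutation Moran's I correlogram with Holm-corrected global test.

    One seeded stream of value shuffles is shared by all distance classes;
    per class the two-sided permutation p-value is
    ``(1 + #{|I_perm - E| >= |I_obs - E|}) / (n_perm + 1)`` with
    ``E = -1/(n-1)`` (``alternative="greater"`` tests positive
    autocorrelation only).  The correlogram is globally significant when the
    smallest Holm-adjusted p-value is <= alpha.
    """
    values = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    if values.size != coords.shape[0]:
        raise SpatialError(
            f"{values.size} values for {coords.shape[0]} coordinates"
        )
    if seed is not None and (not np.isscalar(seed) or int(seed) != seed or seed < 0):
        raise SpatialError(f"invalid seed {seed!r}")
    if n_perm < 1:
        raise SpatialError("n_perm must be positive")
    if n_perm < 99:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value resolution; use >= 99",
            stacklevel=2,
        )
    if alternative not in ("two-sided", "greater"):
        raise SpatialError(f"unknown alternative {alternative!r}")

    classes = distance_classes(coords, n_classes=n_classes, breaks=breaks)
    nonempty = [c for c in range(classes.n_classes) if classes.n_pairs[c] > 0]
    if not nonempty:
        raise SpatialError("no distance class holds any pair")

    n = values.size
    z = values - values.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise SpatialError("values have zero variance")
    expected = -1.0 / (n - 1)

    counts = classes.n_pairs.astype(float)
    i_obs = np.full(classes.n_classes, np.nan)
    i_obs_ne = n * _pair_sums(z, classes)[nonempty] / (counts[nonempty] * denom)
    i_obs[nonempty] = i_obs_ne

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(nonempty))
    obs_dev = (
        np.abs(i_obs_ne - expected) if alternative == "two-sided" else i_obs_ne
    )
    for _ in range(n_perm):
        zp = z[rng.permutation(n)]
        i_perm = n * _pair_sums(zp, classes)[nonempty] / (counts[nonempty] * denom)
        dev = np.abs(i_perm - expected) if alternative == "two-sided" else i_perm
        exceed += dev >= obs_dev - 1e-12

    pvals = np.full(classes.n_classes, np.nan)
    pvals[nonempty] = (1.0 + exceed) / (n_perm + 1.0)
    holm = np.full(classes.n_classes, np.nan)
    holm[nonempty] = holm_adjust(pvals[nonempty])
    significant = bool(np.nanmin(holm[nonempty]) <= alpha)

    return CorrelogramResult(
        class_breaks=classes.breaks,
        class_centers=classes.centers,
        n_pairs=classes.n_pairs,
        morans_i=i_obs,
        expected_i=expected,
        perm_pvalues=pvals,
        holm_pvalues=holm,
        globally_significant=significant,
        alpha=float(alpha),
        n_permutations=int(n_perm),
        seed=None if seed is None else int(seed),
        unreliable=classes.unreliable,
    )
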