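"""Simulated ring datacubes with planted spatial, pulse and trend factors.

The generator draws tree positions uniformly on a rectangular plot, realizes
a spatially autocorrelated between-tree factor (exponential correlation of a
configurable range), a shared temporal trajectory made of pulse events plus
a monotone trend, and composes the cube as

    X[i, j, t] = a_j * s_i + b_j * f_t + c_j * g_t + noise,

where a, b, c are descriptor loadings.  The latent factors are returned so
recovery benchmarks can score how well the analysis pipeline finds them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import spearmanr

from ringpta.datacube import DESCRIPTOR_CODES, RingDatacube

# Default loadings over (RW, LW, RD, ED, LD, MID, MAD, Co, RSD, ESD, LSD):
# the spatial factor loads positively on MAD, LD, RW, Co, RSD; the trend
# loads negatively on ED/MID and positively on LD.
DEFAULT_SPATIAL_LOADINGS = (0.8, 0.3, 0.4, 0.1, 0.9, 0.0, 1.0, 0.9, 0.8, 0.3, 0.5)
DEFAULT_PULSE_LOADINGS = (1.0, 0.6, 0.5, 0.1, 0.8, 0.0, 0.9, 0.7, 0.7, 0.2, 0.4)
DEFAULT_TREND_LOADINGS = (0.2, 0.3, 0.2, -0.8, 0.6, -0.7, 0.4, 0.5, 0.3, -0.2, 0.3)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Configuration of one simulated datacube."""

    n_trees: int = 60
    n_years: int = 30
    start_year: int = 1978
    descriptor_names: tuple = DESCRIPTOR_CODES
    descriptor_loadings_spatial: tuple = DEFAULT_SPATIAL_LOADINGS
    descriptor_loadings_pulse: tuple = DEFAULT_PULSE_LOADINGS
    descriptor_loadings_trend: tuple = DEFAULT_TREND_LOADINGS
    spatial_range_m: float = 30.0
    pulse_years: dict = field(default_factory=dict)  # year -> amplitude
    trend_slope: float = 0.0
    noise_sd: float = 1.0
    plot_size_m: tuple = (80.0, 72.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 3:
            raise SimulationError(f"n_trees must be >= 3, got {self.n_trees}")
        if self.n_years < 2:
            raise SimulationError(f"n_years must be >= 2, got {self.n_years}")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be nonnegative")
        if self.spatial_range_m <= 0:
            raise SimulationError("spatial_range_m must be positive")
        p = len(self.descriptor_names)
        for name, v in (
            ("spatial", self.descriptor_loadings_spatial),
            ("pulse", self.descriptor_loadings_pulse),
            ("trend", self.descriptor_loadings_trend),
        ):
            if len(v) != p:
                raise SimulationError(
                    f"{name} loadings have length {len(v)}, expected {p}"
                )
        years = set(self.years)
        outside = [y for y in self.pulse_years if y not in years]
        if outside:
            raise SimulationError(f"pulse years outside simulated span: {outside}")

    @property
    def years(self) -> list:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class LatentTruth:
    """Ground-truth factors behind one simulated cube."""

    tree_coords: np.ndarray
    spatial_factor: np.ndarray  # per tree, standardized
    temporal_pulse: np.ndarray  # per year, nonzero only at pulse years
    temporal_trend: np.ndarray  # per year, monotone
    seed: int | None


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd <= 0:
        raise SimulationError("degenerate latent factor (zero variance)")
    return (v - v.mean()) / sd


def _spatial_factor(coords: np.ndarray, rho: float, rng) -> np.ndarray:
    """Gaussian process with isotropic exponential correlation exp(-d/rho).

    Falls back to a sum-of-Gaussian-bumps field if the Cholesky factorization
    fails even with jitter.
    """
    d = squareform(pdist(coords))
    C = np.exp(-d / rho)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(C + jitter * np.eye(len(C)))
            return L @ rng.standard_normal(len(C))
        except np.linalg.LinAlgError:
            continue
    warnings.warn(
        "exponential-correlation factorization failed; "
        "falling back to sum-of-bumps spatial field",
        stacklevel=3,
    )
    n_bumps = max(3, int(np.ceil(d.max() / rho)) ** 2)
    centers = rng.uniform(coords.min(axis=0), coords.max(axis=0), size=(n_bumps, 2))
    amp = rng.standard_normal(n_bumps)
    bump_d = cdist(coords, centers)
    return np.exp(-0.5 * (bump_d / rho) ** 2) @ amp


def simulate_cube(config: SimConfig) -> tuple[RingDatacube, LatentTruth]:
    """Generate one datacube and its latent truth; same seed, same output."""
    rng = np.random.default_rng(config.seed)
    n, T = config.n_trees, config.n_years
    p = len(config.descriptor_names)
    years = config.years

    w, h = config.plot_size_m
    coords = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])

    s = _standardize(_spatial_factor(coords, config.spatial_range_m, rng))

    f = np.zeros(T)
    for year, amp in config.pulse_years.items():
        f[years.index(year)] = amp

    if config.trend_slope != 0.0:
        g = config.trend_slope * _standardize(np.arange(T, dtype=float))
    else:
        g = np.zeros(T)

    a = np.asarray(config.descriptor_loadings_spatial, dtype=float)
    b = np.asarray(config.descriptor_loadings_pulse, dtype=float)
    c = np.asarray(config.descriptor_loadings_trend, dtype=float)

    signal = (
        a[None, :, None] * s[:, None, None]
        + b[None, :, None] * f[None, None, :]
        + c[None, :, None] * g[None, None, :]
    )
    values = signal + config.noise_sd * rng.standard_normal((n, p, T))

    cube = RingDatacube(
        values=values,
        tree_ids=[f"T{i + 1:03d}" for i in range(n)],
        descriptor_names=list(config.descriptor_names),
        years=years,
        coords=coords,
    )
    truth = LatentTruth(
        tree_coords=coords,
        spatial_factor=s,
        temporal_pulse=f,
        temporal_trend=g,
        seed=config.seed,
    )
    return cube, truth


def _abs_cor(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise SimulationError(f"length mismatch: {x.size} vs {y.size}")
    if x.std() <= 0 or y.std() <= 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def recovery_metrics(fit: dict, truth: LatentTruth) -> dict:
    """Score how well fitted results recover the planted factors.

    Parameters
    ----------
    fit : dict
        Mapping with optional entries ``"by_year"`` and ``"by_tree"``, each a
        :class:`~ringpta.pipeline.ResultBundle` (or any object exposing a
        ``compromise.row_scores`` array) fitted on the simulated cube.
    truth : LatentTruth
        Ground truth returned by :func:`simulate_cube`.

    Returns
    -------
    dict
        ``spatial_cor``: |cor| between BY_YEAR compromise axis-1 tree scores
        and the planted spatial factor; ``pulse_cor`` / ``trend_cor``:
        best |cor| of the pulse (trend) factor with the first two BY_TREE
        axes; ``pulse_rank_recovery``: fraction of planted pulse years among
        the top-k most extreme BY_TREE axis-1 dates (k = number of pulses);
        ``trend_spearman``: |Spearman rho| of the best trend axis with time;
        ``correlogram_significant`` when a correlogram is in the fit.
    """
    report: dict = {}

    by_year = fit.get("by_year")
    if by_year is not None:
        scores = by_year.compromise.row_scores
        if scores.shape[0] != truth.spatial_factor.size:
            raise SimulationError(
                f"{scores.shape[0]} tree scores for "
                f"{truth.spatial_factor.size} planted values"
            )
        report["spatial_cor"] = _abs_cor(scores[:, 0], truth.spatial_factor)
        corr = getattr(by_year, "correlogram", None)
        if corr is not None:
            report["correlogram_significant"] = bool(corr.globally_significant)

    by_tree = fit.get("by_tree")
    if by_tree is not None:
        scores = by_tree.compromise.row_scores
        T = truth.temporal_pulse.size
        if scores.shape[0] != T:
            raise SimulationError(
                f"{scores.shape[0]} date scores for {T} simulated years"
            )
        n_axes = min(2, scores.shape[1])
        report["pulse_cor"] = max(
            _abs_cor(scores[:, m], truth.temporal_pulse) for m in range(n_axes)
        )
        report["trend_cor"] = max(
            _abs_cor(scores[:, m], truth.temporal_trend) for m in range(n_axes)
        )
        pulse_idx = np.flatnonzero(truth.temporal_pulse)
        if pulse_idx.size:
            extremity = np.abs(scores[:, 0] - np.median(scores[:, 0]))
            top = np.argsort(extremity)[::-1][: pulse_idx.size]
            report["pulse_rank_recovery"] = float(
                np.isin(pulse_idx, top).mean()
            )
        if truth.temporal_trend.any():
            best = int(
                np.argmax(
                    [_abs_cor(scores[:, m], truth.temporal_trend) for m in range(n_axes)]
                )
            )
            rho = spearmanr(scores[:, best], np.arange(T)).statistic
            report["trend_spearman"] = float(abs(rho))

    if not report:
        raise SimulationError("fit contains neither 'by_year' nor 'by_tree' results")
    return report
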