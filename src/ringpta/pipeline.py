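"""End-to-end orchestration: standardize -> interstructure -> compromise ->
intrastructure (-> correlogram), plus serialization of the full result bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

import ringpta
from ringpta.compromise import CompromiseResult, build_compromise, compromise_pca
from ringpta.datacube import Mode, RingDatacube, slice_cube
from ringpta.interstructure import (
    InterstructureResult,
    interstructure_eigen,
    interstructure_matrix,
)
from ringpta.intrastructure import (
    IntrastructureResult,
    envelope_outliers,
    project_tables,
)
from ringpta.preprocess import standardize_stack
from ringpta.spatial_autocorr import CorrelogramResult, correlogram

log = logging.getLogger("ringpta")


class PipelineError(RuntimeError):
    pass


@dataclass
class AnalysisConfig:
    """Numeric conventions of one analysis run, echoed into provenance."""

    r_method: str = "mean_cor"  # mean_cor | rv
    ddof: int = 0
    constant_policy: str = "fail"
    missing_policy: str = "fail"
    center_compromise: bool = False
    rescale_compromise: bool = False
    envelope_probs: tuple = (0.025, 0.975)
    envelope_axis: int = 1
    run_correlogram: bool | None = None  # None: BY_YEAR with coords only
    n_perm: int = 1000
    alpha: float = 0.05
    n_classes: int | None = None
    breaks: tuple | None = None
    alternative: str = "two-sided"
    seed: int | None = None


@dataclass
class ResultBundle:
    mode: Mode
    interstructure: InterstructureResult
    compromise: CompromiseResult
    intrastructure: IntrastructureResult
    correlogram: CorrelogramResult | None
    provenance: dict
    coords: np.ndarray | None = None  # per-tree, for maps


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"[{name}] {exc}") from exc


def run_analysis(
    cube: RingDatacube, mode, config: AnalysisConfig | None = None
) -> ResultBundle:
    """Run the full analysis in one orientation.

    BY_YEAR runs the Moran's I correlogram on the compromise axis-1 tree
    scores whenever coordinates are available (``config.run_correlogram``
    forces either way); the BY_TREE envelope is computed per year across
    trees, mirroring the per-date envelope of the other orientation.
    """
    mode = Mode.coerce(mode)
    cfg = config or AnalysisConfig()

    do_corr = cfg.run_correlogram
    if do_corr is None:
        do_corr = mode is Mode.BY_YEAR and cube.coords is not None
    if do_corr:
        if mode is not Mode.BY_YEAR:
            raise PipelineError(
                "[correlogram] correlogram applies to BY_YEAR tree scores only"
            )
        coords = _stage("correlogram", cube.require_coords)

    log.info("slicing cube %s in mode %s", cube.shape, mode.value)
    stack = _stage("slice", slice_cube, cube, mode, missing=cfg.missing_policy)
    stack = _stage(
        "standardize",
        standardize_stack,
        stack,
        ddof=cfg.ddof,
        constant_policy=cfg.constant_policy,
    )
    log.info(
        "standardized %d tables of shape %s", stack.n_tables, stack.table_shape
    )

    inter = _stage("interstructure", interstructure_matrix, stack, method=cfg.r_method)
    inter = _stage("interstructure", interstructure_eigen, inter)
    log.info(
        "interstructure axes 1-2 inertia: %.1f%% / %.1f%%",
        inter.inertia_pct[0],
        inter.inertia_pct[1] if inter.inertia_pct.size > 1 else float("nan"),
    )

    comp = _stage("compromise", build_compromise, stack, inter)
    comp = _stage(
        "compromise",
        compromise_pca,
        comp,
        center=cfg.center_compromise,
        rescale_columns=cfg.rescale_compromise,
    )
    log.info(
        "compromise axes 1-2 inertia: %.1f%% / %.1f%%",
        comp.inertia_pct[0],
        comp.inertia_pct[1] if comp.inertia_pct.size > 1 else float("nan"),
    )

    intra = _stage("intrastructure", project_tables, stack, comp)
    over = "rows" if mode is Mode.BY_YEAR else "tables"
    intra = _stage(
        "intrastructure",
        envelope_outliers,
        intra,
        probs=cfg.envelope_probs,
        axis=cfg.envelope_axis,
        over=over,
    )

    corr = None
    if do_corr:
        corr = _stage(
            "correlogram",
            correlogram,
            comp.row_scores[:, 0],
            coords,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            alpha=cfg.alpha,
            n_classes=cfg.n_classes,
            breaks=cfg.breaks,
            alternative=cfg.alternative,
        )
        log.info(
            "correlogram globally significant: %s", corr.globally_significant
        )

    provenance = {
        "package": "ringpta",
        "version": ringpta.__version__,
        "mode": mode.value,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "cube_shape": list(cube.shape),
        "descriptors": list(cube.descriptor_names),
        "envelope_over": over,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return ResultBundle(
        mode=mode,
        interstructure=inter,
        compromise=comp,
        intrastructure=intra,
        correlogram=corr,
        provenance=provenance,
        coords=cube.coords,
    )


# ---------------------------------------------------------------------------
# export


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_bundle(bundle: ResultBundle, out_dir, plots: bool = True) -> dict:
    """Write every bundle component as TSV/JSON (+ optional plots).

    Returns the manifest: one entry per file with its sha256 checksum
    (``provenance.json`` carries the run timestamp and is listed without a
    checksum so that re-exports of identical results stay checksum-identical).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise PipelineError(f"output directory not writable: {exc}") from exc

    inter, comp, intra, corr = (
        bundle.interstructure,
        bundle.compromise,
        bundle.intrastructure,
        bundle.correlogram,
    )
    keys = [str(k) for k in inter.table_keys]
    rows = [str(r) for r in comp.row_keys]
    axes_cols = [f"axis{m + 1}" for m in range(comp.n_axes)]

    _write_tsv(
        out / "r_matrix.tsv",
        pd.DataFrame(inter.r_matrix, columns=keys).assign(table=keys)[
            ["table", *keys]
        ],
    )
    _write_tsv(
        out / "interstructure_eigen.tsv",
        pd.DataFrame(
            {
                "component": np.arange(1, inter.eigenvalues.size + 1),
                "eigenvalue": inter.eigenvalues,
                "inertia_pct": inter.inertia_pct,
            }
        ),
    )
    _write_tsv(
        out / "table_scores.tsv",
        pd.DataFrame(
            inter.table_scores,
            columns=[f"axis{m + 1}" for m in range(inter.table_scores.shape[1])],
        ).assign(table=keys)[["table", *(f"axis{m + 1}" for m in range(inter.table_scores.shape[1]))]],
    )
    _write_tsv(
        out / "weights.tsv", pd.DataFrame({"table": keys, "weight": inter.weights})
    )
    _write_tsv(
        out / "compromise_table.tsv",
        pd.DataFrame(comp.table, columns=comp.col_names).assign(row=rows)[
            ["row", *comp.col_names]
        ],
    )
    _write_tsv(
        out / "compromise_eigen.tsv",
        pd.DataFrame(
            {
                "axis": np.arange(1, comp.n_axes + 1),
                "eigenvalue": comp.pca_eigenvalues,
                "inertia_pct": comp.inertia_pct,
            }
        ),
    )
    _write_tsv(
        out / "variable_loadings.tsv",
        pd.DataFrame(comp.variable_loadings, columns=axes_cols).assign(
            descriptor=comp.col_names
        )[["descriptor", *axes_cols]],
    )
    _write_tsv(
        out / "row_scores.tsv",
        pd.DataFrame(comp.row_scores, columns=axes_cols).assign(row=rows)[
            ["row", *axes_cols]
        ],
    )
    _write_tsv(
        out / "outlier_counts.tsv",
        pd.DataFrame(
            {
                "row": rows,
                "outlier_count": intra.outlier_counts,
            }
        ),
    )
    _write_tsv(
        out / "table_outlier_counts.tsv",
        pd.DataFrame(
            {"table": keys, "outlier_count": intra.table_outlier_counts}
        ),
    )
    # tidy per-table descriptor trajectories on the envelope axis
    ax = intra.axis - 1 if intra.axis else 0
    traj = pd.DataFrame(
        [
            (str(k), d, intra.var_coords[ki, dj, ax])
            for ki, k in enumerate(intra.table_keys)
            for dj, d in enumerate(intra.col_names)
        ],
        columns=["table", "descriptor", "coord_axis1"],
    )
    _write_tsv(out / "descriptor_trajectories.tsv", traj)

    if corr is not None:
        _write_tsv(
            out / "correlogram.tsv",
            pd.DataFrame(
                {
                    "center_m": corr.class_centers,
                    "lower_m": corr.class_breaks[:-1],
                    "upper_m": corr.class_breaks[1:],
                    "n_pairs": corr.n_pairs,
                    "morans_i": corr.morans_i,
                    "perm_p": corr.perm_pvalues,
                    "holm_p": corr.holm_pvalues,
                    "unreliable": corr.unreliable,
                }
            ),
        )

    summary = {
        "mode": bundle.mode.value,
        "interstructure_inertia_pct": inter.inertia_pct[:5].tolist(),
        "compromise_inertia_pct": comp.inertia_pct[:5].tolist(),
        "n_tables": inter.n_tables,
        "rows_outside_envelope_at_least_once": int(
            (intra.outlier_counts > 0).sum()
        ),
        "tables_outside_envelope_at_least_once": int(
            (intra.table_outlier_counts > 0).sum()
        ),
        "correlogram_globally_significant": (
            None if corr is None else bool(corr.globally_significant)
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=2, default=str) + "\n"
    )

    if plots:
        from ringpta import reporting

        reporting.render_bundle_plots(bundle, out)

    files = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "files": [
            {
                "name": name,
                "sha256": None if name == "provenance.json" else _sha256(out / name),
            }
            for name in files
        ]
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
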