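"""Matplotlib renderings of the standard analysis figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

_SAVE_KW = {"dpi": 110, "metadata": {"Software": "ringpta"}}


def correlation_circle(loadings, names, inertia_pct, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(theta), np.sin(theta), color="0.7", lw=0.8)
    ax.axhline(0, color="0.85", lw=0.8)
    ax.axvline(0, color="0.85", lw=0.8)
    for j, name in enumerate(names):
        x, y = loadings[j, 0], (loadings[j, 1] if loadings.shape[1] > 1 else 0.0)
        ax.annotate(
            name, (x, y), ha="center", va="center",
            xytext=(0, 0), textcoords="offset points",
        )
        ax.plot([0, x], [0, y], color="0.4", lw=0.6)
    ax.set_xlabel(f"axis 1 ({inertia_pct[0]:.1f}%)")
    if len(inertia_pct) > 1:
        ax.set_ylabel(f"axis 2 ({inertia_pct[1]:.1f}%)")
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def score_map(coords, scores, path, title="axis-1 scores") -> None:
    """Map with symbol area proportional to |score|, shape by sign."""
    scores = np.asarray(scores, dtype=float)
    area = 200.0 * np.abs(scores) / max(np.abs(scores).max(), 1e-12)
    pos, neg = scores >= 0, scores < 0
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(coords[pos, 0], coords[pos, 1], s=area[pos], marker="o",
               facecolors="none", edgecolors="k")
    ax.scatter(coords[neg, 0], coords[neg, 1], s=area[neg], marker="s",
               facecolors="none", edgecolors="k")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def count_map(coords, counts, path, title="envelope departures") -> None:
    counts = np.asarray(counts, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1],
                    s=20 + 15 * counts, c=counts, cmap="viridis")
    fig.colorbar(sc, ax=ax, label="times outside envelope")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def scores_vs_keys(keys, scores, path, xlabel="table") -> None:
    """Axis-1/axis-2 coordinates as a function of the table keys (years)."""
    scores = np.asarray(scores, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(keys))
    ax.plot(x, scores[:, 0], "-o", ms=3, label="axis 1")
    if scores.shape[1] > 1:
        ax.plot(x, scores[:, 1], "--s", ms=3, label="axis 2")
    step = max(1, len(keys) // 10)
    ax.set_xticks(x[::step])
    ax.set_xticklabels([str(k) for k in keys][::step], rotation=45)
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("coordinate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def correlogram_plot(result, path) -> None:
    """Distance-class Moran's I; filled symbols where Holm-significant."""
    fig, ax = plt.subplots(figsize=(6, 4))
    sig = result.holm_pvalues <= result.alpha
    ok = ~np.isnan(result.morans_i)
    ax.plot(result.class_centers[ok], result.morans_i[ok], "-", color="0.4", lw=0.8)
    for c, i, s in zip(result.class_centers[ok], result.morans_i[ok], sig[ok]):
        ax.plot(c, i, "o", mfc="k" if s else "white", mec="k")
    ax.axhline(result.expected_i, color="0.7", ls="--", lw=0.8)
    ax.set_xlabel("distance (m)")
    ax.set_ylabel("Moran's I")
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def render_bundle_plots(bundle, out_dir) -> list:
    """Render every figure applicable to the bundle; returns written paths."""
    out = Path(out_dir)
    comp, intra = bundle.compromise, bundle.intrastructure
    written = []

    p = out / "correlation_circle.png"
    correlation_circle(comp.variable_loadings, comp.col_names, comp.inertia_pct, p)
    written.append(p)

    p = out / "table_scores_vs_keys.png"
    scores_vs_keys(bundle.interstructure.table_keys,
                   bundle.interstructure.table_scores, p)
    written.append(p)

    coords = bundle.coords
    if bundle.mode.value == "by-year":
        if coords is not None:
            p = out / "score_map.png"
            score_map(coords, comp.row_scores[:, 0], p)
            written.append(p)
            p = out / "outlier_map.png"
            count_map(coords, intra.outlier_counts, p)
            written.append(p)
        if bundle.correlogram is not None:
            p = out / "correlogram.png"
            correlogram_plot(bundle.correlogram, p)
            written.append(p)
    else:
        p = out / "date_scores.png"
        scores_vs_keys(comp.row_keys, comp.row_scores, p, xlabel="year")
        written.append(p)
        if coords is not None:
            p = out / "outlier_map.png"
            count_map(coords, intra.table_outlier_counts, p)
            written.append(p)
    return written
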