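"""Ingestion, validation and reorientation of three-way ring datasets.

The central object is :class:`RingDatacube`, a dense ``(trees, descriptors,
years)`` array with tree coordinates.  :func:`slice_cube` reorients it into a
:class:`TableStack` -- the list of two-way tables every downstream stage
consumes -- in either of the two analysis orientations (:class:`Mode`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

#: Default ring-descriptor codes (ring width, latewood percentage, mean/early/
#: latewood density, min/max density, contrast, and the three profile SDs).
DESCRIPTOR_CODES = (
    "RW", "LW", "RD", "ED", "LD", "MID", "MAD", "Co", "RSD", "ESD", "LSD",
)

#: Default column mapping for long-format ring files.  ``descriptors=None``
#: means "every column that is not tree/year/x/y"; ``sep=None`` autodetects
#: tab, comma or whitespace delimiters from the header line.
DEFAULT_SCHEMA = {
    "tree": "tree",
    "year": "year",
    "x": "x",
    "y": "y",
    "descriptors": None,
    "sep": None,
}


class Mode(str, Enum):
    """Slicing orientation of the datacube."""

    BY_YEAR = "by-year"  #: one trees x descriptors table per year
    BY_TREE = "by-tree"  #: one years x descriptors table per tree

    @classmethod
    def coerce(cls, value: "Mode | str") -> "Mode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower().replace("_", "-"))
        except ValueError:
            raise ValueError(
                f"unknown mode {value!r}; expected 'by-year' or 'by-tree'"
            ) from None


class DatacubeError(ValueError):
    """Raised on structural violations of the datacube contracts."""


@dataclass
class RingDatacube:
    """Three-way array of ring descriptors per tree per year.

    Parameters
    ----------
    values : ndarray, shape (n, p, T)
        Descriptor value for (tree i, descriptor j, year t).
    tree_ids : list of str
        Unique tree identifiers, length n.
    descriptor_names : list of str
        Unique descriptor labels, length p.
    years : list of int
        Strictly increasing calendar years, length T.
    coords : ndarray, shape (n, 2), optional
        Planar (x, y) coordinates in meters; ``None`` when unavailable.
    missing_mask : ndarray of bool, shape (n, p, T)
        True where the cell is missing.  Defaults to ``isnan(values)``.
    """

    values: np.ndarray
    tree_ids: list
    descriptor_names: list
    years: list
    coords: np.ndarray | None = None
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DatacubeError(f"values must be 3-d, got shape {self.values.shape}")
        n, p, T = self.values.shape
        self.tree_ids = [str(t) for t in self.tree_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.years = [int(y) for y in self.years]
        if len(self.tree_ids) != n:
            raise DatacubeError(f"{len(self.tree_ids)} tree ids for {n} trees")
        if len(self.descriptor_names) != p:
            raise DatacubeError(
                f"{len(self.descriptor_names)} descriptor names for {p} descriptors"
            )
        if len(self.years) != T:
            raise DatacubeError(f"{len(self.years)} years for {T} year slices")
        for name, labels in (
            ("tree_ids", self.tree_ids),
            ("descriptor_names", self.descriptor_names),
        ):
            if len(set(labels)) != len(labels):
                raise DatacubeError(f"duplicate labels in {name}")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise DatacubeError(f"years must be strictly increasing, got {self.years}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise DatacubeError(
                    f"coords must have shape ({n}, 2), got {self.coords.shape}"
                )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise DatacubeError("missing_mask shape differs from values shape")
        # NaN cells must be declared missing
        undeclared = np.isnan(self.values) & ~self.missing_mask
        if undeclared.any():
            raise DatacubeError(
                f"{int(undeclared.sum())} NaN cells not flagged in missing_mask"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def n_years(self) -> int:
        return self.values.shape[2]

    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def require_coords(self, context: str = "spatial analysis") -> np.ndarray:
        """Return coordinates, raising if absent or incomplete."""
        if self.coords is None:
            raise DatacubeError(f"{context} requested but cube has no coordinates")
        bad = np.isnan(self.coords).any(axis=1)
        if bad.any():
            missing = [self.tree_ids[i] for i in np.flatnonzero(bad)]
            raise DatacubeError(
                f"{context} requested but trees lack coordinates: {missing[:10]}"
            )
        return self.coords


@dataclass
class TableStack:
    """Ordered stack of K same-width two-way tables sliced from a cube.

    ``BY_YEAR`` stacks hold one trees x descriptors table per year (K = T,
    rows shared across tables are trees); ``BY_TREE`` stacks hold one
    years x descriptors table per tree (K = n, shared rows are years).
    """

    mode: Mode
    tables: list
    table_keys: list
    row_keys: list
    col_names: list
    standardized: bool = False
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mode = Mode.coerce(self.mode)
        self.tables = [np.asarray(t, dtype=float) for t in self.tables]
        if len(self.tables) != len(self.table_keys):
            raise DatacubeError("one table key required per table")
        if not self.tables:
            raise DatacubeError("empty table stack")
        shape = self.tables[0].shape
        for k, t in zip(self.table_keys, self.tables):
            if t.shape != shape:
                raise DatacubeError(
                    f"table {k!r} has shape {t.shape}, expected {shape}"
                )
        if shape[0] != len(self.row_keys):
            raise DatacubeError(
                f"{len(self.row_keys)} row keys for tables with {shape[0]} rows"
            )
        if shape[1] != len(self.col_names):
            raise DatacubeError(
                f"{len(self.col_names)} column names for tables with {shape[1]} columns"
            )

    @property
    def n_tables(self) -> int:
        return len(self.tables)

    @property
    def table_shape(self) -> tuple[int, int]:
        return self.tables[0].shape


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def read_long_table(path, schema: dict | None = None) -> RingDatacube:
    """Read a long-format delimited ring file into a :class:`RingDatacube`.

    The file holds one row per tree x year with one column per descriptor;
    ``schema`` maps file columns onto the canonical roles (see
    :data:`DEFAULT_SCHEMA`).  Trees keep file order of first appearance,
    years are sorted increasing, and tree-year rows absent from the file
    become missing-mask entries.

    Raises
    ------
    DatacubeError
        On duplicate (tree, year) rows, non-numeric descriptor cells, or
        inconsistent per-tree coordinates.
    """
    path = Path(path)
    cfg = dict(DEFAULT_SCHEMA)
    cfg.update(schema or {})
    sep = cfg["sep"] or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, engine="python")

    for role in ("tree", "year"):
        if cfg[role] not in df.columns:
            raise DatacubeError(
                f"column {cfg[role]!r} (role {role!r}) not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    tree_col, year_col = cfg["tree"], cfg["year"]
    have_xy = cfg["x"] in df.columns and cfg["y"] in df.columns
    reserved = {tree_col, year_col} | ({cfg["x"], cfg["y"]} if have_xy else set())
    desc_cols = cfg["descriptors"] or [c for c in df.columns if c not in reserved]
    missing_desc = [c for c in desc_cols if c not in df.columns]
    if missing_desc:
        raise DatacubeError(f"descriptor columns not found: {missing_desc}")
    if not desc_cols:
        raise DatacubeError("no descriptor columns identified")

    dup = df.duplicated(subset=[tree_col, year_col], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, [tree_col, year_col]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise DatacubeError(
            f"duplicate (tree, year) entries in {path.name}: {sorted(keys)[:10]}"
        )

    for col in desc_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise DatacubeError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column {col!r} "
                f"at line {row} of {path.name}"
            )
        df[col] = numeric

    tree_ids = list(dict.fromkeys(df[tree_col].astype(str)))
    years = sorted(df[year_col].astype(int).unique())
    tree_pos = {t: i for i, t in enumerate(tree_ids)}
    year_pos = {y: t for t, y in enumerate(years)}

    n, p, T = len(tree_ids), len(desc_cols), len(years)
    values = np.full((n, p, T), np.nan)
    i_idx = df[tree_col].astype(str).map(tree_pos).to_numpy()
    t_idx = df[year_col].astype(int).map(year_pos).to_numpy()
    values[i_idx, :, t_idx] = df[desc_cols].to_numpy(dtype=float)

    coords = None
    if have_xy:
        per_tree = df.groupby(df[tree_col].astype(str))[[cfg["x"], cfg["y"]]]
        spread = per_tree.nunique()
        if (spread > 1).any(axis=None):
            bad_trees = spread.index[(spread > 1).any(axis=1)].tolist()
            raise DatacubeError(f"inconsistent coordinates for trees {bad_trees[:10]}")
        first = per_tree.first()
        coords = first.loc[tree_ids].to_numpy(dtype=float)

    return RingDatacube(
        values=values,
        tree_ids=tree_ids,
        descriptor_names=list(desc_cols),
        years=years,
        coords=coords,
    )


def attach_coords(cube: RingDatacube, path, schema: dict | None = None) -> RingDatacube:
    """Attach coordinates from a separate delimited file (tree, x, y).

    Trees present in the cube but absent from the file get NaN coordinates
    with a warning; the error is deferred to the point where a spatial
    analysis actually needs them.
    """
    path = Path(path)
    cfg = dict(DEFAULT_SCHEMA)
    cfg.update(schema or {})
    sep = cfg["sep"] or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    for role in ("tree", "x", "y"):
        if cfg[role] not in df.columns:
            raise DatacubeError(f"column {cfg[role]!r} not found in {path.name}")
    df = df.drop_duplicates(subset=[cfg["tree"]])
    lookup = {
        str(t): (x, y)
        for t, x, y in df[[cfg["tree"], cfg["x"], cfg["y"]]].itertuples(index=False)
    }
    coords = np.full((cube.n_trees, 2), np.nan)
    absent = []
    for i, tid in enumerate(cube.tree_ids):
        if tid in lookup:
            coords[i] = lookup[tid]
        else:
            absent.append(tid)
    if absent:
        warnings.warn(
            f"{len(absent)} trees lack coordinates (e.g. {absent[:5]}); "
            "spatial analyses will fail for this cube",
            stacklevel=2,
        )
    return RingDatacube(
        values=cube.values,
        tree_ids=cube.tree_ids,
        descriptor_names=cube.descriptor_names,
        years=cube.years,
        coords=coords,
        missing_mask=cube.missing_mask,
    )


def slice_cube(cube: RingDatacube, mode, missing: str = "fail") -> TableStack:
    """Slice the cube into a :class:`TableStack` in the requested orientation.

    ``missing`` controls incomplete cubes: ``"fail"`` (default) raises and
    lists offending cells; ``"drop-tree"`` / ``"drop-year"`` remove every
    tree (year) with any missing cell, with a loud warning.
    """
    mode = Mode.coerce(mode)
    if missing not in ("fail", "drop-tree", "drop-year"):
        raise DatacubeError(f"unknown missing policy {missing!r}")
    values, tree_ids, years = cube.values, cube.tree_ids, cube.years
    mask = cube.missing_mask
    coords = cube.coords
    if mask.any():
        if missing == "fail":
            ii, jj, tt = np.nonzero(mask)
            cells = [
                (tree_ids[i], cube.descriptor_names[j], years[t])
                for i, j, t in zip(ii[:10], jj[:10], tt[:10])
            ]
            raise DatacubeError(
                f"{int(mask.sum())} missing cells with policy 'fail'; first: {cells}"
            )
        if missing == "drop-tree":
            keep = ~mask.any(axis=(1, 2))
            dropped = [t for t, k in zip(tree_ids, keep) if not k]
            warnings.warn(f"dropping {len(dropped)} incomplete trees: {dropped[:10]}")
            values = values[keep]
            tree_ids = [t for t, k in zip(tree_ids, keep) if k]
            coords = coords[keep] if coords is not None else None
            mask = mask[keep]
        else:  # drop-year
            keep = ~mask.any(axis=(0, 1))
            dropped = [y for y, k in zip(years, keep) if not k]
            warnings.warn(f"dropping {len(dropped)} incomplete years: {dropped}")
            values = values[:, :, keep]
            years = [y for y, k in zip(years, keep) if k]

    if mode is Mode.BY_YEAR:
        tables = [values[:, :, t] for t in range(len(years))]
        table_keys, row_keys = list(years), list(tree_ids)
    else:
        tables = [values[i].T for i in range(len(tree_ids))]
        table_keys, row_keys = list(tree_ids), list(years)
    return TableStack(
        mode=mode,
        tables=tables,
        table_keys=table_keys,
        row_keys=row_keys,
        col_names=list(cube.descriptor_names),
        standardized=False,
        coords=coords,
    )


def stack_values(stack: TableStack) -> np.ndarray:
    """Reassemble a stack into the ``(trees, descriptors, years)`` array.

    Inverse of :func:`slice_cube` on complete cubes, used to check that
    slicing is lossless.
    """
    arrs = np.stack(stack.tables)  # (K, rows, p)
    if stack.mode is Mode.BY_YEAR:
        return np.transpose(arrs, (1, 2, 0))  # trees, p, years
    return np.transpose(arrs, (0, 2, 1))  # trees, p, years


def write_cube(cube: RingDatacube, out_dir) -> dict:
    """Serialize a cube as TSVs plus a JSON manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, p, T = cube.shape
    rows = []
    for i, tid in enumerate(cube.tree_ids):
        for t, year in enumerate(cube.years):
            if cube.missing_mask[i, :, t].all():
                continue
            rows.append([tid, year, *cube.values[i, :, t]])
    df = pd.DataFrame(rows, columns=["tree", "year", *cube.descriptor_names])
    df.to_csv(out / "rings.tsv", sep="\t", index=False)
    if cube.coords is not None:
        pd.DataFrame(
            {"tree": cube.tree_ids, "x": cube.coords[:, 0], "y": cube.coords[:, 1]}
        ).to_csv(out / "coords.tsv", sep="\t", index=False)
    manifest = {
        "shape": [n, p, T],
        "tree_ids": cube.tree_ids,
        "descriptor_names": cube.descriptor_names,
        "years": cube.years,
        "has_coords": cube.coords is not None,
        "files": ["rings.tsv"] + (["coords.tsv"] if cube.coords is not None else []),
    }
    (out / "cube.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cube(in_dir) -> RingDatacube:
    """Read a cube serialized by :func:`write_cube`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "cube.json").read_text())
    schema = {"descriptors": manifest["descriptor_names"], "sep": "\t"}
    cube = read_long_table(in_dir / "rings.tsv", schema)
    if manifest["has_coords"]:
        cube = attach_coords(cube, in_dir / "coords.tsv", {"sep": "\t"})
    return cube
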