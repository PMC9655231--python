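"""Spatial data model: lattices, contiguity weights, patch geometry and file I/O.

A study region is represented by a :class:`GridLattice` (unit geometry,
areas, adjacency) and a :class:`CellField` (one case count per unit).
Two lattice flavours are supported:

* regular raster grids, built with :func:`build_regular_grid`, where the
  units are square cells addressed in 0-based row-major order, and
* irregular polygon lattices (e.g. merged administrative cells), built
  with :func:`from_polygons`, where geometry and adjacency come from the
  polygons themselves.

Binary contiguity weights (rook / queen / centroid-distance) are produced
by :func:`contiguity_weights` as sparse matrices.  Patch perimeters, used
by the shape indicators, come from :func:`patch_perimeter`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

__all__ = [
    "GridLattice",
    "CellField",
    "WeightsMatrix",
    "build_regular_grid",
    "from_polygons",
    "contiguity_weights",
    "patch_perimeter",
    "read_field",
    "write_field",
    "write_result",
]


@dataclass(frozen=True)
class GridLattice:
    """Spatial units of the study region.

    Attributes
    ----------
    centroids : ndarray, shape (n, 2)
        Unit centroids (x, y) in a common planar length unit.
    unit_area : ndarray, shape (n,)
        Area of each unit (length unit squared); all positive.
    shape : tuple or None
        ``(nrows, ncols)`` for regular grids, ``None`` for polygon lattices.
    cell_size : float or None
        Cell edge length for regular grids.
    polygons : list of shapely polygons or None
        Unit geometry for irregular lattices.
    """

    centroids: np.ndarray
    unit_area: np.ndarray
    shape: tuple[int, int] | None = None
    cell_size: float | None = None
    polygons: list | None = None

    def __post_init__(self) -> None:
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 2:
            raise ValueError("centroids must have shape (n, 2)")
        if len(self.unit_area) != len(self.centroids):
            raise ValueError("unit_area misaligned with centroids")
        if np.any(self.unit_area <= 0):
            raise ValueError("every unit must have positive area")

    @property
    def n_units(self) -> int:
        return len(self.centroids)

    @property
    def unit_ids(self) -> np.ndarray:
        """Ordered unit identifiers (row-major integers for grids)."""
        return np.arange(self.n_units)

    @property
    def total_area(self) -> float:
        """Total study-region area A (denominator of the area ratio)."""
        return float(self.unit_area.sum())

    @property
    def is_regular(self) -> bool:
        return self.shape is not None

    def adjacency(self, rule: str = "rook") -> list[set[int]]:
        """Contiguous-neighbour sets per unit under ``rule`` (no self links)."""
        w = contiguity_weights(self, rule=rule, include_self=False)
        m = w.matrix.tocsr()
        return [set(m.indices[m.indptr[i]:m.indptr[i + 1]].tolist())
                for i in range(self.n_units)]

    def unit_polygon(self, i: int):
        """Shapely polygon of unit ``i`` (built on demand for grids)."""
        if self.polygons is not None:
            return self.polygons[i]
        nrows, ncols = self.shape
        s = self.cell_size
        r, c = divmod(int(i), ncols)
        return box(c * s, r * s, (c + 1) * s, (r + 1) * s)


@dataclass(frozen=True)
class CellField:
    """One non-negative attribute value (case count) per lattice unit."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("cell values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def total(self) -> float:
        """Total case count N (= C of the scan likelihood ratio)."""
        return float(self.values.sum())


@dataclass(frozen=True)
class WeightsMatrix:
    """Binary spatial weights w_ij under a contiguity or distance rule."""

    rule: str
    include_self: bool
    matrix: sparse.csr_matrix
    threshold: float | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def row_sums(self) -> np.ndarray:
        """W_i = sum_j w_ij for every unit."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def neighbors(self, i: int) -> np.ndarray:
        m = self.matrix
        return m.indices[m.indptr[i]:m.indptr[i + 1]]


def build_regular_grid(nrows: int, ncols: int, cell_size: float = 1.0) -> GridLattice:
    """Build a regular raster lattice of ``nrows`` x ``ncols`` square cells.

    Units are ordered row-major; the centroid of cell (r, c) is
    ``((c + 0.5) * cell_size, (r + 0.5) * cell_size)``.
    """
    if nrows < 1 or ncols < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {nrows} x {ncols}")
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    r, c = np.divmod(np.arange(nrows * ncols), ncols)
    centroids = np.column_stack([(c + 0.5) * cell_size, (r + 0.5) * cell_size])
    unit_area = np.full(nrows * ncols, float(cell_size) ** 2)
    return GridLattice(centroids=centroids, unit_area=unit_area,
                       shape=(nrows, ncols), cell_size=float(cell_size))


def from_polygons(polygons: Sequence) -> GridLattice:
    """Build an irregular lattice from shapely polygons."""
    polygons = list(polygons)
    if not polygons:
        raise ValueError("need at least one polygon")
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polygons])
    unit_area = np.array([p.area for p in polygons])
    return GridLattice(centroids=centroids, unit_area=unit_area, polygons=polygons)


def _grid_contiguity(nrows: int, ncols: int, queen: bool) -> sparse.csr_matrix:
    n = nrows * ncols
    idx = np.arange(n)
    r, c = np.divmod(idx, ncols)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if queen:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = [], []
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        ok = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
        rows.append(idx[ok])
        cols.append(rr[ok] * ncols + cc[ok])
    data = np.ones(sum(len(x) for x in rows), dtype=np.int8)
    return sparse.csr_matrix(
        (data, (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))


def _polygon_contiguity(polygons: Sequence, queen: bool) -> sparse.csr_matrix:
    # rook: shared boundary of positive length; queen: any touch (incl. a point)
    from shapely.strtree import STRtree

    n = len(polygons)
    tree = STRtree(polygons)
    rows, cols = [], []
    for i, p in enumerate(polygons):
        for j in tree.query(p):
            j = int(j)
            if j == i:
                continue
            q = polygons[j]
            if queen:
                linked = p.touches(q) or p.intersects(q)
            else:
                inter = p.boundary.intersection(q.boundary)
                linked = inter.length > 0
            if linked:
                rows.append(i)
                cols.append(j)
    data = np.ones(len(rows), dtype=np.int8)
    m = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    m = ((m + m.T) > 0).astype(np.int8)  # enforce symmetry
    return m


def contiguity_weights(lattice: GridLattice, rule: str = "queen",
                       threshold: float | None = None,
                       include_self: bool = False) -> WeightsMatrix:
    """Binary symmetric spatial weights under ``rule``.

    ``rook`` links edge-sharing units, ``queen`` additionally links
    corner-sharing units, ``distance`` links units whose centroid distance
    is at most ``threshold``.
    """
    if rule not in ("rook", "queen", "distance"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    if rule == "distance":
        if threshold is None:
            raise ValueError("distance rule requires a threshold")
        d2 = ((lattice.centroids[:, None, :] - lattice.centroids[None, :, :]) ** 2).sum(-1)
        m = sparse.csr_matrix((d2 <= threshold ** 2 + 1e-12).astype(np.int8))
        m.setdiag(0)
        m.eliminate_zeros()
    elif lattice.is_regular:
        m = _grid_contiguity(*lattice.shape, queen=(rule == "queen"))
    else:
        if lattice.polygons is None:
            raise ValueError("irregular lattice without polygons cannot use "
                             "contiguity rules; use rule='distance'")
        m = _polygon_contiguity(lattice.polygons, queen=(rule == "queen"))
    if include_self:
        m = m.tolil()
        m.setdiag(1)
        m = m.tocsr()
    m.sort_indices()
    return WeightsMatrix(rule=rule, include_self=include_self,
                         matrix=m.astype(np.int8), threshold=threshold)


def patch_perimeter(lattice: GridLattice, members: Iterable[int]) -> float:
    """Exposed boundary length of the patch formed by ``members``.

    For regular grids this counts cell edges not shared with another member
    (interior holes therefore contribute); for polygon lattices it is the
    boundary length of the polygon union, again including holes.
    """
    members = np.asarray(sorted(set(int(m) for m in members)), dtype=int)
    if members.size == 0:
        raise ValueError("patch perimeter of an empty member set is undefined")
    if np.any(members < 0) or np.any(members >= lattice.n_units):
        raise ValueError("member ids outside the lattice")
    if lattice.is_regular:
        nrows, ncols = lattice.shape
        mask = np.zeros(nrows * ncols, dtype=bool)
        mask[members] = True
        grid = mask.reshape(nrows, ncols)
        shared = (np.count_nonzero(grid[:, :-1] & grid[:, 1:])
                  + np.count_nonzero(grid[:-1, :] & grid[1:, :]))
        return (4 * members.size - 2 * shared) * lattice.cell_size
    union = unary_union([lattice.polygons[i] for i in members])
    return union.boundary.length


# ---------------------------------------------------------------------------
# file I/O
#
# grid-csv: header row,col,value with 0-based integer indices; every cell of
# the bounding (max_row+1) x (max_col+1) grid must be present exactly once.
# GeoJSON: FeatureCollection of polygon features carrying a "count" property
# on input; detection output adds stat / p_value / hotspot / cluster_id.
# ---------------------------------------------------------------------------

def _read_grid_csv(path, cell_size: float) -> tuple[GridLattice, CellField]:
    df = pd.read_csv(path)
    required = {"row", "col", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"grid-csv needs columns row,col,value; got {list(df.columns)}")
    dup = df.duplicated(subset=["row", "col"])
    if dup.any():
        r, c = df.loc[dup.idxmax(), ["row", "col"]]
        raise ValueError(f"duplicate grid cell (row={int(r)}, col={int(c)}) in {path}")
    if (df["value"] < 0).any():
        bad = df.loc[df["value"].idxmin()]
        raise ValueError(f"negative count at (row={int(bad.row)}, col={int(bad.col)})")
    nrows, ncols = int(df["row"].max()) + 1, int(df["col"].max()) + 1
    if (df["row"] < 0).any() or (df["col"] < 0).any():
        raise ValueError("row/col indices must be non-negative")
    if len(df) != nrows * ncols:
        raise ValueError(f"grid-csv incomplete: expected {nrows * ncols} cells, got {len(df)}")
    values = np.zeros(nrows * ncols)
    values[df["row"].to_numpy() * ncols + df["col"].to_numpy()] = df["value"].to_numpy()
    return build_regular_grid(nrows, ncols, cell_size), CellField(values)


def _read_geojson(path) -> tuple[GridLattice, CellField]:
    with open(path) as fh:
        gj = json.load(fh)
    polygons, counts = [], []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if "count" not in props:
            raise ValueError(f"feature {k} in {path} is missing the 'count' property")
        v = float(props["count"])
        if v < 0:
            raise ValueError(f"feature {k} in {path} has a negative count ({v})")
        polygons.append(shape(feat["geometry"]))
        counts.append(v)
    if not polygons:
        raise ValueError(f"no polygon features in {path}")
    return from_polygons(polygons), CellField(np.asarray(counts))


def read_field(path, format: str | None = None,
               cell_size: float = 1.0) -> tuple[GridLattice, CellField]:
    """Read a lattice + count field from grid-csv or GeoJSON."""
    fmt = format or _sniff_format(path)
    if fmt == "grid-csv":
        return _read_grid_csv(path, cell_size)
    if fmt == "geojson":
        return _read_geojson(path)
    raise ValueError(f"unknown format {fmt!r}")


def _sniff_format(path) -> str:
    suffix = Path(path).suffix.lower()
    return "geojson" if suffix in (".geojson", ".json") else "grid-csv"


def write_field(path, lattice: GridLattice, fld: CellField,
                format: str | None = None) -> None:
    """Write a count field; inverse of :func:`read_field` (round-trip safe)."""
    fmt = format or _sniff_format(path)
    if fmt == "grid-csv":
        if not lattice.is_regular:
            raise ValueError("grid-csv output requires a regular lattice")
        nrows, ncols = lattice.shape
        r, c = np.divmod(np.arange(nrows * ncols), ncols)
        pd.DataFrame({"row": r, "col": c, "value": fld.values}).to_csv(path, index=False)
        return
    feats = [{"type": "Feature",
              "geometry": mapping(lattice.unit_polygon(i)),
              "properties": {"unit": int(i), "count": fld.values[i]}}
             for i in range(lattice.n_units)]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_result(path, lattice: GridLattice, labeling,
                 stat: np.ndarray | None = None,
                 p_value: np.ndarray | None = None,
                 format: str | None = None,
                 metadata: dict | None = None) -> None:
    """Serialize a detection result as per-unit records.

    ``labeling`` is a :class:`hotgrid.lisa.HotspotLabeling`-like object with
    ``mask`` and ``cluster_id`` arrays.  Output columns per unit: id,
    statistic, p-value, hotspot flag, cluster id (grid outputs add row/col).
    """
    n = lattice.n_units
    stat = np.full(n, np.nan) if stat is None else np.asarray(stat, dtype=float)
    p_value = np.full(n, np.nan) if p_value is None else np.asarray(p_value, dtype=float)
    fmt = format or _sniff_format(path)
    if fmt == "grid-csv":
        cols = {"unit": np.arange(n)}
        if lattice.is_regular:
            r, c = np.divmod(np.arange(n), lattice.shape[1])
            cols.update(row=r, col=c)
        cols.update(stat=stat, p_value=p_value,
                    hotspot=labeling.mask.astype(int),
                    cluster_id=labeling.cluster_id)
        pd.DataFrame(cols).to_csv(path, index=False)
        return
    feats = []
    for i in range(n):
        feats.append({"type": "Feature",
                      "geometry": mapping(lattice.unit_polygon(i)),
                      "properties": {
                          "unit": int(i),
                          "stat": None if np.isnan(stat[i]) else float(stat[i]),
                          "p_value": None if np.isnan(p_value[i]) else float(p_value[i]),
                          "hotspot": bool(labeling.mask[i]),
                          "cluster_id": int(labeling.cluster_id[i]),
                      }})
    doc = {"type": "FeatureCollection", "features": feats}
    if metadata:
        doc["metadata"] = metadata
    with open(path, "w") as fh:
        json.dump(doc, fh)
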