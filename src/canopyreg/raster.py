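"""Core gridded domain types: binary rasters, land-use maps, tract partitions.

The measurement substrate of the package is a planar binary raster (tree
canopy, or greenspace extracted from a land-cover product), a categorical
land-use surface, and a partition of the study area into analysis tracts.
Rasters are stored row-major with row 0 at the *top* (image convention);
the planar origin refers to the lower-left corner of the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, shape, mapping

# Land-use categories, grouped by the greenspace access class they imply.
PRIVATE_CLASSES = ("residential", "commercial", "office", "industrial")
SEMI_PUBLIC_CLASSES = ("golf", "education", "cemetery", "agriculture")
PUBLIC_CLASSES = ("park_recreation",)
OTHER_CLASSES = ("other",)
LANDUSE_CATEGORIES = PRIVATE_CLASSES + SEMI_PUBLIC_CLASSES + PUBLIC_CLASSES + OTHER_CLASSES

_CATEGORY_CODE = {name: i for i, name in enumerate(LANDUSE_CATEGORIES)}


@dataclass
class BinaryRaster:
    """A gridded 0/1 surface with square cells in planar units.

    Parameters
    ----------
    grid : ndarray of shape (nrows, ncols)
        Values exactly 0 or 1; dtype coerced to uint8.
    cell_size : float
        Edge length of one cell in planar units (e.g. feet or metres).
    origin : (float, float)
        Planar (x, y) of the lower-left corner of the grid.
    """

    grid: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError(f"grid must be 2-D, got ndim={g.ndim}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        vals = np.unique(g)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("raster values must be exactly 0 or 1")
        self.grid = g.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Planar (x, y) centres of cells; optionally only where ``mask`` is true."""
        nrows, ncols = self.grid.shape
        rows, cols = np.indices((nrows, ncols))
        if mask is not None:
            rows, cols = rows[mask], cols[mask]
        x0, y0 = self.origin
        x = x0 + (cols + 0.5) * self.cell_size
        # row 0 is the top row of the grid
        y = y0 + (nrows - rows - 0.5) * self.cell_size
        return np.column_stack([x.ravel(), y.ravel()])


@dataclass
class LandUseMap:
    """Categorical land-use surface on the same grid as the rasters.

    Stored as an integer label grid indexing into ``LANDUSE_CATEGORIES``.
    Every cell carries exactly one category, so the categories partition
    the study area by construction.
    """

    labels: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if lab.min() < 0 or lab.max() >= len(LANDUSE_CATEGORIES):
            raise ValueError("label codes outside the known category roster")
        self.labels = lab.astype(np.int16)

    def category_grid(self) -> np.ndarray:
        cats = np.array(LANDUSE_CATEGORIES)
        return cats[self.labels]

    @staticmethod
    def code(category: str) -> int:
        try:
            return _CATEGORY_CODE[category]
        except KeyError:
            raise KeyError(
                f"unknown land-use category {category!r}; known: {LANDUSE_CATEGORIES}"
            ) from None


@dataclass
class TractPartition:
    """Non-overlapping tracts tiling the study area.

    Carries both a per-cell label grid (``tract_of_cell``, -1 outside any
    tract) and per-tract square/polygon geometry, so that raster zonal
    operations and polygon IO stay consistent.
    """

    tract_ids: list[str]
    tract_of_cell: np.ndarray  # int label grid, index into tract_ids
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    geometries: dict[str, Polygon] = field(default_factory=dict)
    layout: tuple[int, int] | None = None  # (n_rows, n_cols) when regular

    def __post_init__(self) -> None:
        if len(set(self.tract_ids)) != len(self.tract_ids):
            raise ValueError("tract_ids must be unique")
        self.tract_of_cell = np.asarray(self.tract_of_cell, dtype=np.int32)

    @property
    def n_tracts(self) -> int:
        return len(self.tract_ids)

    def mask(self, tract_id: str) -> np.ndarray:
        idx = self.tract_ids.index(tract_id)
        return self.tract_of_cell == idx

    def areas(self) -> dict[str, float]:
        """Planar area of each tract (cell count x cell area)."""
        counts = np.bincount(
            self.tract_of_cell[self.tract_of_cell >= 0].ravel(),
            minlength=self.n_tracts,
        )
        a = self.cell_size**2
        out = {tid: float(c * a) for tid, c in zip(self.tract_ids, counts)}
        if any(v <= 0 for v in out.values()):
            empty = [t for t, v in out.items() if v <= 0]
            raise ValueError(f"tracts with zero area: {empty}")
        return out


# ---------------------------------------------------------------------------
# IO: ESRI ASCII grid for rasters / label grids, GeoJSON for partitions
# ---------------------------------------------------------------------------

def write_ascii_grid(path, grid: np.ndarray, cell_size: float,
                     origin: tuple[float, float] = (0.0, 0.0),
                     nodata: int = -9999) -> None:
    """Write an integer grid in the ESRI ASCII raster dialect."""
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1]:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in np.asarray(grid, dtype=np.int64):
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float], int]:
    """Read an ESRI ASCII grid; returns (grid, cell_size, origin, nodata)."""
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([int(float(v)) for v in parts])
    grid = np.array(rows, dtype=np.int64)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared dimensions")
    return (
        grid,
        header["cellsize"],
        (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        int(header.get("nodata_value", -9999)),
    )


def write_binary_raster(path, raster: BinaryRaster) -> None:
    write_ascii_grid(path, raster.grid, raster.cell_size, raster.origin)


def read_binary_raster(path) -> BinaryRaster:
    grid, cell, origin, _ = read_ascii_grid(path)
    return BinaryRaster(grid, cell, origin)


def write_partition_geojson(path, partition: TractPartition) -> None:
    features = []
    for tid in partition.tract_ids:
        geom = partition.geometries.get(tid)
        if geom is None:
            raise ValueError(f"tract {tid} has no polygon geometry to serialize")
        features.append(
            {"type": "Feature",
             "properties": {"tract_id": tid},
             "geometry": mapping(geom)}
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_partition_geojson(path, cell_size: float,
                           grid_shape: tuple[int, int],
                           origin: tuple[float, float] = (0.0, 0.0)) -> TractPartition:
    """Load tract polygons and rasterize membership by cell-centre containment."""
    with open(path) as fh:
        doc = json.load(fh)
    ids, geoms = [], {}
    for feat in doc["features"]:
        tid = str(feat["properties"]["tract_id"])
        ids.append(tid)
        geoms[tid] = shape(feat["geometry"])
    label = np.full(grid_shape, -1, dtype=np.int32)
    probe = BinaryRaster(np.zeros(grid_shape, dtype=np.uint8), cell_size, origin)
    centers = probe.cell_centers()
    from shapely import points, contains  # vectorised containment
    pts = points(centers)
    for i, tid in enumerate(ids):
        inside = contains(geoms[tid], pts).reshape(grid_shape)
        label[inside] = i
    return TractPartition(ids, label, cell_size, origin, geoms)
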