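"""Per-tract tree and greenspace landscape metrics.

Six variables per tract, computed from a binary canopy raster, a binary
greenspace raster, a land-use map, and a tract partition:

- ``TreeCov``  — fraction of tract area under tree canopy;
- ``TreeClus`` — median area of the connected canopy patches in the tract;
- ``TreeAgr``  — average nearest-neighbour index (NNI) of patch centroids:
  observed mean nearest-neighbour distance over the expectation
  ``0.5 / sqrt(n / A)`` under complete spatial randomness.  NNI < 1 reads
  as clustering, > 1 as dispersion;
- ``PrvtGrn``, ``SemiGrn``, ``GrnRec`` — fractions of tract area in
  greenspace on private (residential/commercial/office/industrial),
  semi-public (golf/education/cemetery/agriculture) and public
  (parks & recreation) land.

Patches are delineated within each tract independently (a canopy crossing
a tract boundary is split), with 8-neighbour connectivity by default so
diagonally touching crowns read as one canopy.  A cell belongs to the
tract containing its centre.  Metrics that need >= 1 patch (TreeClus) or
>= 2 patches (TreeAgr) are flagged undefined rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .raster import (
    BinaryRaster,
    LandUseMap,
    TractPartition,
    PRIVATE_CLASSES,
    SEMI_PUBLIC_CLASSES,
    PUBLIC_CLASSES,
    LANDUSE_CATEGORIES,
)

METRIC_COLUMNS = ["TreeCov", "TreeClus", "TreeAgr", "PrvtGrn", "SemiGrn", "GrnRec"]


@dataclass
class Patch:
    """Maximal connected set of canopy cells inside one tract."""

    cells: np.ndarray  # (m, 2) array of (row, col) indices
    area: float        # cell count x cell area
    centroid: np.ndarray  # planar (x, y) mean of member-cell centres

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("patch area must be positive")


def _check_frames(*layers) -> None:
    sizes = {round(l.cell_size, 12) for l in layers}
    shapes = {l.grid.shape if hasattr(l, "grid") else
              (l.labels.shape if hasattr(l, "labels") else l.tract_of_cell.shape)
              for l in layers}
    if len(sizes) > 1 or len(shapes) > 1:
        raise ValueError(
            f"layers do not share a coordinate frame: cell sizes {sizes}, shapes {shapes}"
        )


def extract_patches(raster: BinaryRaster, tract_mask: np.ndarray,
                    connectivity: int = 8) -> list[Patch]:
    """Connected canopy patches within one tract.

    Parameters
    ----------
    raster : binary canopy raster.
    tract_mask : boolean grid selecting the tract's cells.
    connectivity : 4 or 8 (edge-only or edge+corner adjacency).

    An empty intersection yields an empty list, not an error.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    inside = (raster.grid == 1) & tract_mask
    if not inside.any():
        return []
    # skimage connectivity: 1 = edges only, 2 = edges + corners
    labels = measure.label(inside, connectivity=1 if connectivity == 4 else 2)
    patches = []
    cell_area = raster.cell_area
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        cells = np.argwhere(mask)
        centroid = raster.cell_centers(mask).mean(axis=0)
        patches.append(Patch(cells=cells, area=len(cells) * cell_area,
                             centroid=centroid))
    return patches


def tree_cover_fraction(raster: BinaryRaster, tract_mask: np.ndarray) -> float:
    """Canopy cells in the tract x cell area / tract area, in [0, 1]."""
    n_cells = int(tract_mask.sum())
    if n_cells == 0:
        raise ValueError("tract has zero area on this raster")
    return float(((raster.grid == 1) & tract_mask).sum()) / n_cells


def median_patch_size(patches: list[Patch]) -> float:
    """Median patch area; even counts take the mean of the two central values."""
    if not patches:
        raise ValueError("median patch size undefined for an empty patch list")
    return float(np.median([p.area for p in patches]))


def nearest_neighbor_index(centroids: np.ndarray, area: float) -> float:
    """Average nearest-neighbour index of a point set in a region of given area.

    ``NNI = D_obs / D_exp`` with ``D_obs`` the mean distance from each point
    to its nearest other point and ``D_exp = 0.5 / sqrt(n / area)``, the
    expected mean under complete spatial randomness.  No edge correction is
    applied, which biases small samples slightly upward near boundaries.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("NNI requires at least 2 centroids")
    if area <= 0:
        raise ValueError("area must be positive")
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(pts, k=2)
    d_obs = float(d[:, 1].mean())
    d_exp = 0.5 / np.sqrt(len(pts) / area)
    return d_obs / d_exp


def classify_greenspace(green: BinaryRaster, landuse: LandUseMap,
                        tract_mask: np.ndarray) -> tuple[float, float, float]:
    """Split a tract's greenspace by land-use access class.

    Returns (PrvtGrn, SemiGrn, GrnRec) as fractions of total tract area.
    Green cells on the residual 'other' class are counted as unclassified
    and contribute to none of the three fractions, so their sum never
    exceeds the tract's overall green fraction.
    """
    _check_frames(green, landuse)
    n_cells = int(tract_mask.sum())
    if n_cells == 0:
        raise ValueError("tract has zero area on this raster")
    g = (green.grid == 1) & tract_mask
    cats = np.array(LANDUSE_CATEGORIES)[landuse.labels]
    out = []
    for group in (PRIVATE_CLASSES, SEMI_PUBLIC_CLASSES, PUBLIC_CLASSES):
        out.append(float((g & np.isin(cats, group)).sum()) / n_cells)
    return tuple(out)


def compute_tract_metrics(canopy: BinaryRaster, green: BinaryRaster,
                          landuse: LandUseMap, partition: TractPartition,
                          connectivity: int = 8) -> pd.DataFrame:
    """Assemble all six per-tract metrics into a DataFrame.

    Columns: the six metrics plus ``n_patches`` and a ``flags`` column
    listing any metric left undefined for the tract (TreeClus with zero
    patches, TreeAgr with fewer than two).  Undefined metrics are NaN.
    """
    _check_frames(canopy, green, landuse, partition)
    if canopy.grid.shape != partition.tract_of_cell.shape:
        raise ValueError("raster and partition grids differ in shape")
    areas = partition.areas()
    rows = []
    for tid in partition.tract_ids:
        mask = partition.mask(tid)
        patches = extract_patches(canopy, mask, connectivity=connectivity)
        flags = []
        tree_cov = tree_cover_fraction(canopy, mask)
        if patches:
            tree_clus = median_patch_size(patches)
        else:
            tree_clus, flags = np.nan, flags + ["TreeClus undefined (no patches)"]
        if len(patches) >= 2:
            cents = np.array([p.centroid for p in patches])
            tree_agr = nearest_neighbor_index(cents, areas[tid])
        else:
            tree_agr = np.nan
            flags.append("TreeAgr undefined (<2 patches)")
        pg, sg, gr = classify_greenspace(green, landuse, mask)
        rows.append({
            "tract_id": tid, "TreeCov": tree_cov, "TreeClus": tree_clus,
            "TreeAgr": tree_agr, "PrvtGrn": pg, "SemiGrn": sg, "GrnRec": gr,
            "n_patches": len(patches), "flags": ";".join(flags),
        })
    return pd.DataFrame(rows).set_index("tract_id")
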