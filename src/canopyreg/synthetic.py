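"""Synthetic landscapes, covariates, and spatially autocorrelated outcomes.

The study this package supports joins per-tract landscape metrics (canopy
cover, patch size, patch clustering, land-use-stratified greenspace) with
socio-demographic and air-quality covariates and regresses a health-outcome
rate on them with spatial lag / spatial error models.  The real inputs of
such a study (county canopy rasters, parcel land use, tract health tables)
are access-restricted, so this module generates all of them with a known
data-generating process:

- a regular grid of square tracts;
- clustered binary canopy grown from random seed cells by noisy isotropic
  dilation, with direct control over cover, patch count, and compactness;
- contiguous land-use blocks per tract spanning private, semi-public and
  public categories, with class-specific greenspace shares;
- correlated Gaussian covariates mapped to documented tract-level ranges;
- an outcome rate drawn from a spatial lag process
  ``y = (I - rho W)^-1 (X beta + eps)``, a spatial error process
  ``y = X beta + (I - lambda W)^-1 u``, or plain ``y = X beta + eps``.

Every generator is a pure function of its configuration and an integer
seed, so datasets are bit-reproducible.  The true parameters are recorded
in a :class:`SyntheticTruth` next to each dataset, making parameter
recovery testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .raster import BinaryRaster, LandUseMap, TractPartition, LANDUSE_CATEGORIES
from .weights import SpatialWeights, eigenvalue_bounds

COVARIATE_COLUMNS = ["PovRt", "EduAtn", "EtnGrp", "ChldPop", "SnrPop", "PM25", "Ozone"]

# Per-column (mean, sd, lower, upper) used to map standard-normal draws to
# realistic tract-level scales; percentages are clipped to [0, 100].
COVARIATE_SCALES = {
    "PovRt": (18.82, 13.01, 0.0, 100.0),
    "EduAtn": (41.79, 21.90, 0.0, 100.0),
    "EtnGrp": (8.17, 13.08, 0.0, 100.0),
    "ChldPop": (12.80, 4.26, 0.0, 100.0),
    "SnrPop": (11.02, 6.05, 0.0, 100.0),
    "PM25": (11.53, 1.28, 0.0, np.inf),
    "Ozone": (0.05, 0.01, 0.0, np.inf),
}


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic outcome draw.

    ``process`` is one of ``lag``, ``error``, ``none``; the spatial
    parameter (``rho`` for lag, ``lambda_`` for error) must lie strictly
    inside the admissible interval of the weight matrix used.
    """

    process: str
    beta: np.ndarray          # coefficients, intercept first
    sigma: float
    seed: int
    rho: float | None = None
    lambda_: float | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.process not in ("lag", "error", "none"):
            raise ValueError(f"unknown process {self.process!r}")
        self.beta = np.asarray(self.beta, dtype=float)
        if self.process == "lag" and self.rho is None:
            raise ValueError("lag process requires rho")
        if self.process == "error" and self.lambda_ is None:
            raise ValueError("error process requires lambda_")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = self.beta.tolist()
        return d


def simulate_partition(n_rows: int, n_cols: int, tract_cells: int,
                       cell_size: float = 1.0) -> tuple[TractPartition, BinaryRaster]:
    """Regular grid of square tracts, each ``tract_cells`` cells on a side.

    Returns the partition and an all-zero raster on the matching grid.
    """
    for name, v in (("n_rows", n_rows), ("n_cols", n_cols),
                    ("tract_cells", tract_cells)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    H, Wd = n_rows * tract_cells, n_cols * tract_cells
    rows, cols = np.indices((H, Wd))
    label = (rows // tract_cells) * n_cols + (cols // tract_cells)
    ids = [f"T{r:03d}{c:03d}" for r in range(n_rows) for c in range(n_cols)]
    side = tract_cells * cell_size
    geoms = {}
    for r in range(n_rows):
        for c in range(n_cols):
            # planar y grows upward; tract row 0 is the top of the grid
            x0, y1 = c * side, (n_rows - r) * side
            geoms[ids[r * n_cols + c]] = box(x0, y1 - side, x0 + side, y1)
    part = TractPartition(ids, label.astype(np.int32), cell_size,
                          origin=(0.0, 0.0), geometries=geoms,
                          layout=(n_rows, n_cols))
    empty = BinaryRaster(np.zeros((H, Wd), dtype=np.uint8), cell_size)
    return part, empty


def simulate_canopy(partition: TractPartition, target_cover,
                    patch_intensity: float = 0.002, patch_growth: float = 4.0,
                    seed: int = 0) -> BinaryRaster:
    """Clustered binary canopy with per-tract cover control.

    Within each tract, seed cells are drawn uniformly at an expected density
    of ``patch_intensity`` seeds per unit area (at least one), and canopy is
    grown outward by selecting the cells with the smallest noisy distance to
    the nearest seed until the tract's target cover is met.  ``patch_growth``
    sets compactness: large values give near-isotropic discs around few
    seeds (large, aggregated patches, low NNI); small values give ragged,
    fragmented growth.

    Realized cover equals the target to within one cell per tract
    (rounding of the target cell count).
    """
    covers = _per_tract(target_cover, partition)
    if np.any((covers < 0) | (covers >= 1)):
        raise ValueError("target_cover must lie in [0, 1) per tract")
    if patch_intensity <= 0:
        raise ValueError("patch_intensity must be positive")
    if patch_growth <= 0:
        raise ValueError("patch_growth must be positive")
    rng = np.random.default_rng(seed)
    grid = np.zeros(partition.tract_of_cell.shape, dtype=np.uint8)
    areas = partition.areas()
    for k, tid in enumerate(partition.tract_ids):
        cover = covers[k]
        mask = partition.tract_of_cell == k
        n_cells = int(mask.sum())
        n_target = int(round(cover * n_cells))
        # one uniform draw per tract even when empty, to keep the stream
        # alignment independent of the cover configuration
        n_seeds = max(1, rng.poisson(patch_intensity * areas[tid]))
        if n_target == 0:
            continue
        cells = np.argwhere(mask)
        seed_idx = rng.choice(len(cells), size=min(n_seeds, len(cells)),
                              replace=False)
        seed_mask = np.zeros_like(mask)
        seed_mask[tuple(cells[seed_idx].T)] = True
        # distance (in cells) to the nearest seed, computed on the tract's
        # bounding box so tracts stay independent
        r0, c0 = cells.min(axis=0)
        r1, c1 = cells.max(axis=0) + 1
        dist = ndimage.distance_transform_edt(~seed_mask[r0:r1, c0:c1])
        # spatially smooth noise keeps the selected sublevel set connected:
        # the patches grow as ragged blobs, not as salt-and-pepper speckle
        white = rng.standard_normal(dist.shape)
        noise = ndimage.gaussian_filter(white, sigma=2.0, mode="nearest")
        noise *= dist.max() / patch_growth
        score = np.where(mask[r0:r1, c0:c1], dist + noise, np.inf)
        flat = np.argsort(score, axis=None, kind="stable")[:n_target]
        sel = np.unravel_index(flat, score.shape)
        sub = grid[r0:r1, c0:c1]
        sub[sel] = 1
    return BinaryRaster(grid, partition.cell_size, partition.origin)


def simulate_landuse_and_green(partition: TractPartition,
                               class_shares: dict[str, float],
                               green_share_by_class: dict[str, float],
                               seed: int = 0,
                               nonresidential_tracts: tuple[str, ...] = (),
                               share_concentration: float | None = None,
                               green_concentration: float | None = None,
                               ) -> tuple[LandUseMap, BinaryRaster]:
    """Contiguous land-use blocks per tract plus the implied greenspace raster.

    Each tract is split into vertical strips whose widths realise
    ``class_shares`` (largest-remainder rounding at cell resolution); the
    strip order is shuffled per tract.  Within each strip, the first
    ``round(share * cells)`` cells in raster order are marked green, so a
    class's green fraction is exact to within one cell per block.

    With ``share_concentration`` (resp. ``green_concentration``) set, each
    tract's class shares are drawn from a Dirichlet centred on
    ``class_shares`` (resp. each class's green share from a Beta centred
    on its configured value) with the given concentration, so tracts vary
    around the stated composition instead of repeating it exactly.

    Tracts named in ``nonresidential_tracts`` are overridden to be entirely
    public parkland with the park class's green share — the synthetic
    analogue of tracts without residential land that the study design
    excludes.
    """
    shares = dict(class_shares)
    tot = sum(shares.values())
    if not np.isclose(tot, 1.0, atol=1e-9):
        raise ValueError(f"class_shares must sum to 1, got {tot}")
    for d in (shares, green_share_by_class):
        for cat, v in d.items():
            if cat not in LANDUSE_CATEGORIES:
                raise KeyError(f"unknown land-use category {cat!r}")
            if not 0 <= v <= 1:
                raise ValueError(f"share for {cat!r} outside [0, 1]: {v}")
    rng = np.random.default_rng(seed)
    shape = partition.tract_of_cell.shape
    labels = np.full(shape, LandUseMap.code("other"), dtype=np.int16)
    green = np.zeros(shape, dtype=np.uint8)
    cats = [c for c, s in shares.items() if s > 0]
    for k, tid in enumerate(partition.tract_ids):
        mask = partition.tract_of_cell == k
        cells = np.argwhere(mask)
        r0, c0 = cells.min(axis=0)
        r1, c1 = cells.max(axis=0) + 1
        width = c1 - c0
        if tid in nonresidential_tracts:
            tract_cats, widths = ["park_recreation"], [width]
        else:
            order = list(rng.permutation(len(cats)))
            tract_cats = [cats[i] for i in order]
            s = np.array([shares[c] for c in tract_cats])
            if share_concentration is not None:
                s = rng.dirichlet(share_concentration * s)
            widths = _largest_remainder(s * width, width)
        col = c0
        for cat, w in zip(tract_cats, widths):
            if w == 0:
                continue
            block = np.zeros(shape, dtype=bool)
            block[r0:r1, col:col + w] = True
            block &= mask
            labels[block] = LandUseMap.code(cat)
            gshare = green_share_by_class.get(cat, 0.0)
            if green_concentration is not None and 0.0 < gshare < 1.0:
                gshare = rng.beta(gshare * green_concentration,
                                  (1.0 - gshare) * green_concentration)
            n_green = int(round(gshare * block.sum()))
            if n_green > 0:
                bc = np.argwhere(block)  # row-major: fills from the top
                green[tuple(bc[:n_green].T)] = 1
            col += w
    return (LandUseMap(labels, partition.cell_size, partition.origin),
            BinaryRaster(green, partition.cell_size, partition.origin))


def simulate_covariates(n_tracts: int, correlation: np.ndarray | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Correlated tract covariates on documented scales.

    Draws standard multivariate normals with the given correlation matrix
    (order: ``COVARIATE_COLUMNS``; default: mild r = 0.3 within the
    socio-demographic block, independence elsewhere), maps each column to
    its (mean, sd) scale and clips to its admissible range.
    """
    if n_tracts <= 0:
        raise ValueError("n_tracts must be positive")
    p = len(COVARIATE_COLUMNS)
    if correlation is None:
        correlation = default_covariate_correlation()
    C = np.asarray(correlation, dtype=float)
    if C.shape != (p, p) or not np.allclose(C, C.T):
        raise ValueError(f"correlation must be a symmetric {p}x{p} matrix")
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_tracts, p)) @ L.T
    data = {}
    for j, col in enumerate(COVARIATE_COLUMNS):
        mean, sd, lo, hi = COVARIATE_SCALES[col]
        data[col] = np.clip(mean + sd * z[:, j], lo, hi)
    return pd.DataFrame(data)


def default_covariate_correlation(socio_r: float = 0.3) -> np.ndarray:
    """Mild positive correlation among the five socio-demographic columns."""
    p = len(COVARIATE_COLUMNS)
    C = np.eye(p)
    socio = [COVARIATE_COLUMNS.index(c)
             for c in ("PovRt", "EduAtn", "EtnGrp", "ChldPop", "SnrPop")]
    for i in socio:
        for j in socio:
            if i != j:
                C[i, j] = socio_r
    return C


def simulate_outcome(X: np.ndarray, W: SpatialWeights,
                     truth: SyntheticTruth) -> np.ndarray:
    """Draw the outcome rate from the configured spatial process.

    lag:   ``y = (I - rho W)^-1 (X beta + eps)``,  eps ~ N(0, sigma^2 I)
    error: ``y = X beta + (I - lambda W)^-1 u``,   u  ~ N(0, sigma^2 I)
    none:  ``y = X beta + eps``
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n != W.n:
        raise ValueError(f"X has {n} rows but W has {W.n} observations")
    if X.shape[1] != len(truth.beta):
        raise ValueError("beta length does not match X columns")
    rng = np.random.default_rng(truth.seed)
    noise = rng.standard_normal(n) * truth.sigma
    xb = X @ truth.beta
    if truth.process == "none":
        return xb + noise
    param = truth.rho if truth.process == "lag" else truth.lambda_
    lo, hi = eigenvalue_bounds(W)
    if not (1.0 / lo < param < 1.0 / hi):
        raise ValueError(
            f"spatial parameter {param} outside admissible interval "
            f"({1.0 / lo:.4f}, {1.0 / hi:.4f})"
        )
    A = np.eye(n) - param * W.matrix
    if truth.process == "lag":
        return np.linalg.solve(A, xb + noise)
    return xb + np.linalg.solve(A, noise)


# ---------------------------------------------------------------------------
# One-call dataset assembly for the pipeline and acceptance tests
# ---------------------------------------------------------------------------

# Default coefficients of the outcome process (intercept first, then the six
# landscape metrics and seven covariates), mirroring the magnitudes a
# tract-level asthma ER-visit-rate regression produces.
DEFAULT_BETA = {
    "const": 7.586,
    "TreeCov": -44.692, "TreeClus": -0.034, "TreeAgr": 15.687,
    "PrvtGrn": -12.998, "SemiGrn": -1.567, "GrnRec": 3.876,
    "PovRt": 0.172, "EduAtn": -0.003, "EtnGrp": 0.365,
    "ChldPop": 0.843, "SnrPop": -0.105, "PM25": 0.583, "Ozone": 114.113,
}

DEFAULT_CLASS_SHARES = {
    "residential": 0.55, "commercial": 0.12, "industrial": 0.08,
    "education": 0.07, "park_recreation": 0.08, "golf": 0.04, "other": 0.06,
}

DEFAULT_GREEN_SHARES = {
    "residential": 0.25, "commercial": 0.08, "industrial": 0.04,
    "education": 0.35, "park_recreation": 0.70, "golf": 0.85, "other": 0.0,
}


@dataclass
class SyntheticDataset:
    partition: TractPartition
    canopy: BinaryRaster
    landuse: LandUseMap
    green: BinaryRaster
    metrics: pd.DataFrame
    covariates: pd.DataFrame
    table: pd.DataFrame          # metrics + covariates + outcome, per tract
    weights: SpatialWeights
    truth: SyntheticTruth


def make_dataset(n_rows: int = 10, n_cols: int = 10, tract_cells: int = 20,
                 cell_size: float = 1.0, process: str = "lag",
                 rho: float = 0.541, lambda_: float = 0.797,
                 sigma: float = 13.0, beta: dict[str, float] | None = None,
                 target_cover=0.11, cover_sd: float = 0.06,
                 patch_intensity: float = 0.02, patch_growth: float = 4.0,
                 n_nonresidential: int = 0, seed: int = 0) -> SyntheticDataset:
    """Generate a complete synthetic study dataset with recorded truth.

    Defaults give a 10x10 lattice of 20x20-cell tracts with per-tract
    canopy cover drawn from a Beta distribution (mean ``target_cover``,
    SD ``cover_sd`` — the spread real tract-level cover shows) and a
    spatial-lag outcome (rho = 0.541, sigma = 13 rate units), matching
    the scale of a tract-level ER-visit-rate analysis.  All randomness
    derives from ``seed``.
    """
    from .metrics import compute_tract_metrics
    from .weights import build_queen_weights, row_standardize

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    partition, _ = simulate_partition(n_rows, n_cols, tract_cells, cell_size)
    nonres = tuple(partition.tract_ids[i] for i in range(n_nonresidential))
    if np.isscalar(target_cover) and cover_sd > 0:
        mu = float(target_cover)
        nu = mu * (1 - mu) / cover_sd**2 - 1.0
        if nu <= 0:
            raise ValueError("cover_sd too large for the given mean cover")
        rng_cov = np.random.default_rng(seeds[4])
        target_cover = np.clip(
            rng_cov.beta(mu * nu, (1 - mu) * nu, size=partition.n_tracts),
            0.0, 0.95)
    canopy = simulate_canopy(partition, target_cover, patch_intensity,
                             patch_growth, seed=seeds[0])
    landuse, green = simulate_landuse_and_green(
        partition, DEFAULT_CLASS_SHARES, DEFAULT_GREEN_SHARES,
        seed=seeds[1], nonresidential_tracts=nonres,
        share_concentration=50.0, green_concentration=30.0)
    metrics = compute_tract_metrics(canopy, green, landuse, partition)
    covariates = simulate_covariates(partition.n_tracts, seed=seeds[2])
    covariates.index = pd.Index(partition.tract_ids, name="tract_id")
    W = row_standardize(build_queen_weights(partition))
    bdict = dict(DEFAULT_BETA if beta is None else beta)
    feat = [c for c in bdict if c != "const"]
    table = metrics.join(covariates)
    Xdf = table[feat].fillna(0.0)  # flagged tracts get placeholder features;
    # they are excluded by the pipeline filter before estimation
    X = np.column_stack([np.ones(len(Xdf)), Xdf.to_numpy()])
    truth = SyntheticTruth(
        process=process, beta=np.array([bdict["const"]] + [bdict[c] for c in feat]),
        sigma=sigma, seed=seeds[3],
        rho=rho if process == "lag" else None,
        lambda_=lambda_ if process == "error" else None,
        feature_names=["const"] + feat)
    y = simulate_outcome(X, W, truth)
    table = table.copy()
    table["Asthma"] = y
    table["residential_share"] = _residential_share(landuse, partition)
    return SyntheticDataset(partition, canopy, landuse, green, metrics,
                            covariates, table, W, truth)


def _residential_share(landuse: LandUseMap, partition: TractPartition) -> np.ndarray:
    res = landuse.labels == LandUseMap.code("residential")
    out = np.empty(partition.n_tracts)
    for k in range(partition.n_tracts):
        mask = partition.tract_of_cell == k
        out[k] = res[mask].mean()
    return out


def _per_tract(value, partition: TractPartition) -> np.ndarray:
    if np.isscalar(value):
        return np.full(partition.n_tracts, float(value))
    if isinstance(value, dict):
        return np.array([float(value[t]) for t in partition.tract_ids])
    arr = np.asarray(value, dtype=float)
    if arr.shape != (partition.n_tracts,):
        raise ValueError("per-tract value has wrong length")
    return arr


def _largest_remainder(raw: np.ndarray, total: int) -> list[int]:
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()
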