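"""Contiguity spatial weights for tract lattices.

Builds the row-standardized weight matrix W that enters the spatial lag
model (the neighbour-average Wy term) and the spatial error model, plus
the eigenvalue machinery that defines the admissible interval for the
spatial parameter and the log-determinant term of the likelihood.

For W = D^-1 B with B a symmetric binary adjacency and D the degree
diagonal, W is similar to the symmetric matrix S = D^-1/2 B D^-1/2, so
its spectrum is real; the largest eigenvalue of a row-standardized,
island-free W is exactly 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .raster import TractPartition


@dataclass
class SpatialWeights:
    """Spatial weight matrix with adjacency bookkeeping.

    Attributes
    ----------
    ids : list of tract identifiers, fixing row/column order.
    matrix : (n, n) dense array of weights, zero diagonal.
    standardized : True when every non-island row sums to 1.
    islands : ids of observations without neighbours.
    """

    ids: list[str]
    matrix: np.ndarray
    standardized: bool = False
    islands: list[str] = field(default_factory=list)
    _eigvals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if W.shape != (n, n):
            raise ValueError(f"matrix shape {W.shape} does not match {n} ids")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        self.matrix = W
        self.islands = [self.ids[i] for i in np.flatnonzero(W.sum(axis=1) == 0)]

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def neighbors(self) -> dict[str, list[str]]:
        out = {}
        for i, tid in enumerate(self.ids):
            out[tid] = [self.ids[j] for j in np.flatnonzero(self.matrix[i])]
        return out

    def lag(self, x: np.ndarray) -> np.ndarray:
        """Spatial lag Wx (neighbour average when standardized)."""
        return self.matrix @ np.asarray(x, dtype=float)

    def eigenvalues(self) -> np.ndarray:
        """Real spectrum of W via the similar symmetric matrix.

        Valid for W derived from a symmetric binary adjacency (possibly
        row-standardized). Cached after the first call.
        """
        if self._eigvals is None:
            W = self.matrix
            if self.standardized:
                deg = (W > 0).sum(axis=1).astype(float)
                if np.any(deg == 0):
                    raise ValueError(
                        "islands present: spectrum of the standardized matrix "
                        "is undefined; drop islands first"
                    )
                d = np.sqrt(deg)
                B = W * deg[:, None]  # recover binary adjacency
                if not np.allclose(B, B.T):
                    raise ValueError("underlying adjacency is not symmetric")
                S = B / np.outer(d, d)
                self._eigvals = scipy.linalg.eigvalsh(S)
            else:
                if not np.allclose(W, W.T):
                    raise ValueError("non-symmetric unstandardized matrix")
                self._eigvals = scipy.linalg.eigvalsh(W)
        return self._eigvals

    def subset(self, keep_ids: list[str]) -> "SpatialWeights":
        """Restrict to a subset of observations (re-standardizing if needed)."""
        idx = [self.ids.index(t) for t in keep_ids]
        sub = self.matrix[np.ix_(idx, idx)]
        w = SpatialWeights(list(keep_ids), sub, standardized=False)
        if self.standardized:
            # recover binary adjacency before re-standardizing
            w = SpatialWeights(list(keep_ids), (sub > 0).astype(float))
            return row_standardize(w)
        return w


def build_queen_weights(partition: TractPartition) -> SpatialWeights:
    """First-order queen contiguity: shared edge or corner makes neighbours."""
    return _build_contiguity(partition, queen=True)


def build_rook_weights(partition: TractPartition) -> SpatialWeights:
    """First-order rook contiguity: shared edge only."""
    return _build_contiguity(partition, queen=False)


def _build_contiguity(partition: TractPartition, queen: bool) -> SpatialWeights:
    lab = partition.tract_of_cell
    n = partition.n_tracts
    adj = np.zeros((n, n), dtype=float)
    shifts = [(0, 1), (1, 0)]
    if queen:
        shifts += [(1, 1), (1, -1)]
    for dr, dc in shifts:
        a = lab[max(dr, 0): lab.shape[0] + min(dr, 0),
                max(dc, 0): lab.shape[1] + min(dc, 0)]
        b = lab[max(-dr, 0): lab.shape[0] + min(-dr, 0),
                max(-dc, 0): lab.shape[1] + min(-dc, 0)]
        ok = (a >= 0) & (b >= 0) & (a != b)
        pairs = np.unique(np.column_stack([a[ok], b[ok]]), axis=0)
        for i, j in pairs:
            adj[i, j] = adj[j, i] = 1.0
    return SpatialWeights(list(partition.tract_ids), adj, standardized=False)


def build_knn_weights(coords: np.ndarray, ids: list[str], k: int) -> SpatialWeights:
    """k-nearest-neighbour adjacency, symmetrized (i~j if either is in the
    other's k nearest); included as a configuration alternative."""
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    _, nn = tree.query(coords, k=k + 1)
    n = len(ids)
    adj = np.zeros((n, n))
    for i in range(n):
        for j in nn[i, 1:]:
            adj[i, j] = adj[j, i] = 1.0
    return SpatialWeights(list(ids), adj)


def row_standardize(W: SpatialWeights) -> SpatialWeights:
    """Scale each non-island row to sum to 1. Idempotent; islands stay zero."""
    rs = W.matrix.sum(axis=1)
    if np.all(rs == 0):
        warnings.warn("all observations are islands; standardization is a no-op")
        return SpatialWeights(list(W.ids), W.matrix.copy(), standardized=True)
    out = W.matrix.copy()
    nz = rs > 0
    out[nz] = out[nz] / rs[nz, None]
    if W.islands:
        warnings.warn(f"islands left unstandardized (zero rows): {W.islands}")
    return SpatialWeights(list(W.ids), out, standardized=True)


def eigenvalue_bounds(W: SpatialWeights) -> tuple[float, float]:
    """(min, max) eigenvalue of W; the admissible spatial-parameter interval
    is (1/min, 1/max), i.e. (1/omega_min, 1) for standardized island-free W."""
    ev = W.eigenvalues()
    return float(ev.min()), float(ev.max())


# ---------------------------------------------------------------------------
# Serialization: GAL neighbour lists and a JSON adjacency dump
# ---------------------------------------------------------------------------

def write_gal(path, W: SpatialWeights) -> None:
    order = sorted(W.ids)
    nbrs = W.neighbors
    with open(path, "w") as fh:
        fh.write(f"{W.n}\n")
        for tid in order:
            ns = sorted(nbrs[tid])
            fh.write(f"{tid} {len(ns)}\n")
            fh.write(" ".join(ns) + "\n")


def read_gal(path) -> SpatialWeights:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    lines = [ln for ln in tokens if ln.strip()]
    n = int(lines[0].split()[0])
    pairs: dict[str, list[str]] = {}
    i = 1
    while i < len(lines):
        tid, cnt = lines[i].split()
        cnt = int(cnt)
        ns = lines[i + 1].split() if cnt > 0 else []
        if len(ns) != cnt:
            raise ValueError(f"GAL entry for {tid} declares {cnt} neighbours, found {len(ns)}")
        pairs[tid] = ns
        i += 2
    ids = sorted(pairs)
    if len(ids) != n:
        raise ValueError("GAL header count does not match entries")
    index = {t: i for i, t in enumerate(ids)}
    adj = np.zeros((n, n))
    for tid, ns in pairs.items():
        for nb in ns:
            adj[index[tid], index[nb]] = 1.0
    return SpatialWeights(ids, adj)


def write_weights_json(path, W: SpatialWeights) -> None:
    doc = {
        "ids": list(W.ids),
        "standardized": W.standardized,
        "neighbors": {t: sorted(ns) for t, ns in W.neighbors.items()},
        "weights": {
            t: {W.ids[j]: W.matrix[i, j] for j in np.flatnonzero(W.matrix[i])}
            for i, t in enumerate(W.ids)
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
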