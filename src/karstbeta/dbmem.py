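"""Distance-based Moran's eigenvector maps (dbMEM / PCNM).

Spatial predictors are built from cell centroids: the Euclidean distance
matrix is truncated at threshold t (default: the longest edge of the
minimum spanning tree, which keeps the <= t graph connected), distances
above t are replaced by the conventional 4t, and the modified matrix is
submitted to principal-coordinate analysis.  Positive-eigenvalue axes are
the candidate eigenfunctions; each gets a Moran's I computed with binary
connectivity weights (w_ij = 1 iff d_ij <= t), and axes with I strictly
above the no-autocorrelation expectation E(I) = -1/(n-1) are the retained
broad-to-fine-scale spatial descriptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .census import site_ids_for_grain
from .errors import ComputationError, ValidationError
from .grid import PlotGeometry

EIGEN_TOL = 1e-9  # axes with lambda <= EIGEN_TOL * lambda_max are numerical zeros


def cell_centroids(geometry: PlotGeometry, grain: float):
    """(site_ids, coords) for the grain's cell grid; centroid of (i, j) is
    ((i + 0.5) g, (j + 0.5) g), ordered like every other per-site table."""
    ids = site_ids_for_grain(geometry, grain)
    coords = np.array([((i + 0.5) * grain, (j + 0.5) * grain) for i, j in ids])
    return ids, coords


@dataclass
class MEMBasis:
    """PCoA axes of the truncated spatial distance matrix.

    ``vectors`` columns are unit-norm, mean-centred eigenvectors (sign fixed
    so the largest-magnitude loading is positive), sorted by descending
    eigenvalue; ``moran_i`` aligns with the columns.
    """

    coords: np.ndarray
    truncation: float
    eigenvalues: np.ndarray
    vectors: np.ndarray
    moran_i: np.ndarray
    retained: np.ndarray  # boolean, I > E(I)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def expected_i(self) -> float:
        return -1.0 / (self.n - 1)

    def selected(self) -> "MEMBasis":
        """Subset with only the axes whose Moran's I exceeds E(I)."""
        keep = self.retained
        if not keep.any():
            warnings.warn("no eigenvector with Moran's I above E(I)", stacklevel=2)
        return replace(
            self,
            eigenvalues=self.eigenvalues[keep],
            vectors=self.vectors[:, keep],
            moran_i=self.moran_i[keep],
            retained=np.ones(int(keep.sum()), dtype=bool),
        )


def _mst_truncation(dist_sq: np.ndarray) -> float:
    mst = minimum_spanning_tree(dist_sq)
    return float(mst.data.max())


def moran_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with an arbitrary (here binary) weight matrix, zero diagonal."""
    z = values - values.mean()
    s0 = weights.sum()
    if s0 == 0:
        raise ComputationError("empty spatial weight matrix")
    denom = z @ z
    if denom == 0:
        raise ComputationError("constant values: Moran's I undefined")
    return float(len(z) / s0 * (z @ weights @ z) / denom)


def build_dbmem(coords: np.ndarray, truncation: float | None = None) -> MEMBasis:
    """Construct the dbMEM basis from site coordinates (metres)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValidationError("need >= 3 sites with 2-D coordinates")
    d = pdist(coords)
    if d.min() <= 0:
        raise ValidationError("duplicate coordinates")
    dist_sq = squareform(d)
    t = _mst_truncation(dist_sq) if truncation is None else float(truncation)

    dstar = np.where(dist_sq > t + 1e-12, 4.0 * t, dist_sq)
    np.fill_diagonal(dstar, 0.0)
    n = coords.shape[0]
    # Gower double-centring of -1/2 D*^2
    a = -0.5 * dstar**2
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    lam_max = evals[0]
    if lam_max <= 0:
        raise ComputationError("no positive eigenvalue: degenerate configuration")
    keep = evals > EIGEN_TOL * lam_max
    evals, evecs = evals[keep], evecs[:, keep]
    # reproducible sign: largest-magnitude loading positive
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]

    w = ((dist_sq <= t + 1e-12) & (dist_sq > 0)).astype(float)
    ivals = np.array([moran_i(evecs[:, k], w) for k in range(evecs.shape[1])])
    e_i = -1.0 / (n - 1)
    return MEMBasis(
        coords=coords,
        truncation=t,
        eigenvalues=evals,
        vectors=evecs,
        moran_i=ivals,
        retained=ivals > e_i,
    )


def select_mem(basis: MEMBasis) -> MEMBasis:
    """Axes with Moran's I strictly greater than E(I) = -1/(n-1)."""
    return basis.selected()
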