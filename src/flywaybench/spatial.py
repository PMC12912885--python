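"""Spatial structures for the count GLMMs.

Five options, in increasing order of complexity:

``none``
    no spatial term.
``ri_grid``
    random intercept of 100 x 100 km grid-cell identity (sites grouped to
    cells via a local equirectangular projection).
``bps``
    two-dimensional basis-penalty smooth of site coordinates, represented in
    mixed-model form: a low-rank radial basis at spread knots whose
    coefficients are iid random effects with an estimated variance (the
    standard smoothing-penalty / random-effect equivalence).
``grf`` / ``grf_barrier``
    low-rank (knot-based, predictive-process) Gaussian random field with
    exponential covariance and estimated range and SD; knots are a greedy
    thinning of the site coordinates at a minimum spacing (the mesh cutoff,
    decimal degrees).  The barrier variant removes knot-graph edges that
    cross a physical barrier (e.g. a coastline) and replaces euclidean
    distances by graph geodesics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

__all__ = ["SpatialSpec", "STRUCTURE_IDS", "grid_cell_ids", "farthest_point_knots",
           "thin_knots", "bps_basis", "GrfBasis"]

STRUCTURE_IDS = ("none", "ri_grid", "bps", "grf", "grf_barrier")

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


@dataclass(frozen=True)
class SpatialSpec:
    """One spatial-structure choice."""

    structure_id: str = "none"
    grid_cell_km: float = 100.0
    mesh_cutoff_deg: float = 0.5
    bps_basis_dim: int = 30
    barrier: np.ndarray | None = None  # polyline, shape (k, 2) lon/lat

    def __post_init__(self) -> None:
        if self.structure_id not in STRUCTURE_IDS:
            raise ValueError(f"structure_id must be one of {STRUCTURE_IDS}")
        if self.grid_cell_km <= 0 or self.mesh_cutoff_deg <= 0:
            raise ValueError("grid_cell_km and mesh_cutoff_deg must be > 0")
        if self.structure_id == "grf_barrier" and self.barrier is None:
            raise ValueError("grf_barrier requires a barrier geometry")

    @property
    def label(self) -> str:
        if self.structure_id in ("grf", "grf_barrier"):
            return f"{self.structure_id}_{self.mesh_cutoff_deg}"
        return self.structure_id


def _project_km(coords: np.ndarray) -> np.ndarray:
    """Local equirectangular projection (km), evaluated at the mean latitude."""
    lat0 = coords[:, 1].mean()
    x = coords[:, 0] * KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(lat0))
    y = coords[:, 1] * KM_PER_DEG_LAT
    return np.column_stack([x, y])


def grid_cell_ids(coords: np.ndarray, cell_km: float = 100.0) -> np.ndarray:
    """Integer grid-cell label per site for the grid random intercept."""
    xy = _project_km(coords)
    ij = np.floor(xy / cell_km).astype(int)
    _, labels = np.unique(ij, axis=0, return_inverse=True)
    return labels


def farthest_point_knots(coords: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point subsample of ``k`` knot locations."""
    n = len(coords)
    if k >= n:
        return coords.copy()
    chosen = [0]
    d = np.linalg.norm(coords - coords[0], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return coords[np.sort(chosen)]


def thin_knots(coords: np.ndarray, cutoff_deg: float) -> np.ndarray:
    """Greedy thinning: keep a site if no kept site is within ``cutoff_deg``."""
    kept: list[int] = []
    for i, c in enumerate(coords):
        if all(np.linalg.norm(c - coords[j]) >= cutoff_deg for j in kept):
            kept.append(i)
    return coords[kept]


def bps_basis(coords: np.ndarray, basis_dim: int = 30) -> np.ndarray:
    """Low-rank Gaussian radial basis of the 2-D coordinate smooth.

    Returns an (n_sites, k) design matrix; the smoothing penalty is realised
    by treating the k coefficients as iid random effects.
    """
    knots = farthest_point_knots(coords, min(basis_dim, len(coords)))
    d = cdist(coords, knots)
    dk = cdist(knots, knots)
    scale = np.median(dk[dk > 0]) / 2.0 if len(knots) > 1 else 1.0
    return np.exp(-0.5 * (d / scale) ** 2)


def _segments_intersect(p1, p2, q1, q2) -> bool:
    """2-D segment intersection (proper or touching)."""
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    d1, d2 = orient(q1, q2, p1), orient(q1, q2, p2)
    d3, d4 = orient(p1, p2, q1), orient(p1, p2, q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True
    return False


class GrfBasis:
    """Knot-based Gaussian-field basis with exponential covariance.

    ``design(range_deg)`` returns Z such that ``Z @ w`` with ``w ~ N(0, sd^2 I)``
    has (approximately) the predictive-process covariance
    ``sd^2 * K_sk K_kk^{-1} K_ks`` at the sites.
    """

    def __init__(self, coords: np.ndarray, cutoff_deg: float = 0.5,
                 barrier: np.ndarray | None = None):
        self.coords = np.asarray(coords, float)
        self.knots = thin_knots(self.coords, cutoff_deg)
        self.cutoff = cutoff_deg
        if barrier is not None:
            self._build_barrier_distances(np.asarray(barrier, float))
        else:
            self.d_kk = cdist(self.knots, self.knots)
            self.d_sk = cdist(self.coords, self.knots)

    def _build_barrier_distances(self, barrier: np.ndarray) -> None:
        """Graph geodesic distances with barrier-crossing edges removed."""
        pts = np.vstack([self.knots, self.coords])
        n = len(pts)
        d = cdist(pts, pts)
        # connect each point to its nearest neighbours, excluding edges that
        # cross any barrier segment
        kn = min(8, n - 1)
        adj = np.full((n, n), np.inf)
        segs = list(zip(barrier[:-1], barrier[1:]))
        for i in range(n):
            order = np.argsort(d[i])[1:kn + 1]
            for j in order:
                if any(_segments_intersect(pts[i], pts[j], a, b) for a, b in segs):
                    continue
                adj[i, j] = adj[j, i] = d[i, j]
        geo = shortest_path(adj, method="D", directed=False)
        # disconnected pairs fall back to a large multiple of the extent
        finite = geo[np.isfinite(geo)]
        cap = 10.0 * (finite.max() if finite.size else 1.0)
        geo = np.where(np.isfinite(geo), geo, cap)
        nk = len(self.knots)
        self.d_kk = geo[:nk, :nk]
        self.d_sk = geo[nk:, :nk]

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def design(self, range_deg: float) -> np.ndarray:
        k_kk = np.exp(-self.d_kk / range_deg)
        k_kk[np.diag_indices_from(k_kk)] += 1e-8
        k_sk = np.exp(-self.d_sk / range_deg)
        # geodesic kernels need not be PD: clip the spectrum
        w, v = np.linalg.eigh(k_kk)
        w = np.clip(w, 1e-8, None)
        inv_sqrt = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
        return k_sk @ inv_sqrt
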