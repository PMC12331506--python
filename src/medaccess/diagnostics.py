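"""Point-pattern and supply–demand mismatch diagnostics.

Kernel density estimation highlights over- and under-served areas; the
standard deviational ellipse summarises the directional spread of a facility
tier; bivariate Moran's I with permutation inference locates statistically
significant mismatch clusters (high-population / low-supply and their
converses); population centroids track demand shift between snapshots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp

from ._util import round_half_up
from .synthetic_city import AdminUnit, PopulationGrid

ClusterClass = Literal["HH", "LL", "HL", "LH", "not-significant"]


# ---------------------------------------------------------------------------
# kernel density estimation


@dataclass
class DensityRaster:
    grid: PopulationGrid  # geometry carrier; values field unused
    values: np.ndarray  # (n_rows, n_cols), >= 0
    bandwidth_m: float
    kernel: str
    n_points: int


def _quartic(u: np.ndarray) -> np.ndarray:
    """Finite-support quartic (biweight) kernel, unit integral on the disk."""
    out = np.zeros_like(u)
    inside = u < 1.0
    out[inside] = (3.0 / math.pi) * (1.0 - u[inside] ** 2) ** 2
    return out


def _gaussian(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u**2) / (2.0 * math.pi)


_KERNELS = {"quartic": _quartic, "gaussian": _gaussian}


def default_bandwidth(extent_m: tuple[float, float]) -> float:
    """1/30 of the extent diagonal — a pragmatic smoothing default."""
    return math.hypot(*extent_m) / 30.0


def kernel_density(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None,
    h: float,
    grid: PopulationGrid,
    kernel: str = "quartic",
) -> DensityRaster:
    """D(x, y) = (1/h^2) * sum_i w_i K(d((x,y),(x_i,y_i)) / h) at cell centers."""
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("kernel_density requires at least one point")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    kfun = _KERNELS[kernel]
    gx, gy = grid.cell_centers()
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    values = np.zeros(len(cells))
    for start in range(0, len(pts), 512):
        chunk, cw = pts[start : start + 512], w[start : start + 512]
        u = np.linalg.norm(cells[:, None, :] - chunk[None, :, :], axis=2) / h
        values += kfun(u) @ cw
    values /= h**2
    return DensityRaster(grid, values.reshape(gx.shape), h, kernel, len(pts))


# ---------------------------------------------------------------------------
# standard deviational ellipse


@dataclass
class DeviationEllipse:
    """Center, principal-axis standard deviations and major-axis azimuth.

    ``theta_deg`` is measured clockwise from north (grid azimuth convention),
    in [0, 180); ``sigma_x`` is the spread along the major axis (>= sigma_y).
    """

    center: tuple[float, float]
    sigma_x: float
    sigma_y: float
    theta_deg: float
    degenerate: bool = False


def deviation_ellipse(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> DeviationEllipse:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(np.unique(pts, axis=0)) < 2:
        raise ValueError("deviation_ellipse requires at least 2 distinct points")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    W = w.sum()
    cx, cy = (w @ pts[:, 0]) / W, (w @ pts[:, 1]) / W
    dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
    sxx = (w @ (dx * dx)) / W
    syy = (w @ (dy * dy)) / W
    sxy = (w @ (dx * dy)) / W
    # closed-form principal-axis solution
    phi = 0.5 * math.atan2(2.0 * sxy, sxx - syy)  # major axis, CCW from east
    half_sum = 0.5 * (sxx + syy)
    half_diff = math.hypot(0.5 * (sxx - syy), sxy)
    sigma_major = math.sqrt(max(half_sum + half_diff, 0.0))
    sigma_minor = math.sqrt(max(half_sum - half_diff, 0.0))
    theta = (90.0 - math.degrees(phi)) % 180.0
    degenerate = sigma_minor < 1e-12 * max(sigma_major, 1.0)
    if degenerate:
        warnings.warn("collinear points: deviational ellipse degenerates to a line")
    return DeviationEllipse((cx, cy), sigma_major, sigma_minor, theta, degenerate)


def ellipse_polygon(ellipse: DeviationEllipse, n_segments: int = 64) -> list[tuple[float, float]]:
    """Closed ring approximating the 1-sigma ellipse (for GeoJSON output)."""
    phi = math.radians(90.0 - ellipse.theta_deg)
    c, s = math.cos(phi), math.sin(phi)
    ring = []
    for k in range(n_segments + 1):
        t = 2 * math.pi * k / n_segments
        ex, ey = ellipse.sigma_x * math.cos(t), ellipse.sigma_y * math.sin(t)
        ring.append((ellipse.center[0] + c * ex - s * ey, ellipse.center[1] + s * ex + c * ey))
    return ring


# ---------------------------------------------------------------------------
# spatial weights


@dataclass
class SpatialWeights:
    """Sparse spatial weights with zero diagonal."""

    ids: list
    matrix: sp.csr_matrix
    row_standardized: bool = False

    def __post_init__(self) -> None:
        m = self.matrix.tocsr()
        if np.any(m.diagonal() != 0):
            raise ValueError("spatial weights must have zero diagonal")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.ids)

    def standardized(self) -> "SpatialWeights":
        """Row-standardized copy (nonzero rows sum to 1)."""
        if self.row_standardized:
            return self
        m = self.matrix.astype(float).tolil()
        sums = np.asarray(self.matrix.sum(axis=1)).ravel()
        if np.any(sums == 0):
            warnings.warn("disconnected spatial weights: some units have no neighbors")
        scale = np.divide(1.0, sums, out=np.zeros_like(sums, dtype=float), where=sums > 0)
        m = sp.diags(scale) @ self.matrix
        return SpatialWeights(self.ids, sp.csr_matrix(m), row_standardized=True)

    @classmethod
    def queen_from_polygons(cls, polygons: Sequence, ids: Sequence | None = None) -> "SpatialWeights":
        """Queen contiguity: units sharing any boundary point are neighbors."""
        n = len(polygons)
        ids = list(range(n)) if ids is None else list(ids)
        rows, cols = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if polygons[i].intersects(polygons[j]):
                    rows += [i, j]
                    cols += [j, i]
        m = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return cls(ids, m)

    @classmethod
    def rook_grid(cls, n_rows: int, n_cols: int) -> "SpatialWeights":
        """Rook contiguity on a regular grid, row-major unit order."""
        n = n_rows * n_cols
        rows, cols = [], []
        for r in range(n_rows):
            for c in range(n_cols):
                i = r * n_cols + c
                if c + 1 < n_cols:
                    rows += [i, i + 1]
                    cols += [i + 1, i]
                if r + 1 < n_rows:
                    j = i + n_cols
                    rows += [i, j]
                    cols += [j, i]
        m = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return cls(list(range(n)), m)


# ---------------------------------------------------------------------------
# bivariate Moran's I


@dataclass
class MoranResult:
    I: float
    p_value: float
    n_permutations: int
    local_I: np.ndarray
    local_p: np.ndarray
    clusters: list[ClusterClass]
    x_mean: float
    y_mean: float
    n: int


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError(f"zero variance in {name}")
    return (v - v.mean()) / sd


def bivariate_moran(
    x: Sequence[float],
    y: Sequence[float],
    w: SpatialWeights,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    units: Sequence[AdminUnit] | None = None,
) -> MoranResult:
    """Bivariate Moran's I of x against the spatial lag of y.

    Both variables are z-standardized and the weights row-standardized, so
    I = z_x . (W z_y) / n; with y = x this reduces to univariate Moran's I.
    The pseudo p-value is two-sided, from ``n_perm`` permutations of y;
    local cluster classes (HH/LL/HL/LH) use the conditional permutation
    scheme and are assigned only where the local pseudo-p <= alpha.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(xv)
    if n < 4:
        raise ValueError("bivariate_moran requires at least 4 units")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    zx = _zscore(xv, "x")
    zy = _zscore(yv, "y")
    ws = w.standardized()
    W = ws.matrix
    lag = W @ zy
    I_obs = float(zx @ lag) / n

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    I_perm = (W @ zy[perms].T).T @ zx / n  # (n_perm,)
    p_global = (np.count_nonzero(np.abs(I_perm) >= abs(I_obs)) + 1) / (n_perm + 1)

    local_I = zx * lag
    local_p = np.ones(n)
    W_lil = W.tolil()
    for i in range(n):
        neigh = np.array(W_lil.rows[i], dtype=int)
        if neigh.size == 0:
            continue
        wts = np.array(W_lil.data[i])
        others = np.delete(zy, i)
        draws = rng.choice(len(others), size=(n_perm, neigh.size))
        lag_i = (others[draws] * wts).sum(axis=1)
        li_perm = zx[i] * lag_i
        local_p[i] = (np.count_nonzero(np.abs(li_perm) >= abs(local_I[i])) + 1) / (n_perm + 1)

    clusters: list[ClusterClass] = []
    for i in range(n):
        if local_p[i] > alpha:
            clusters.append("not-significant")
        else:
            hi_x, hi_y = zx[i] > 0, lag[i] > 0
            clusters.append(
                "HH" if hi_x and hi_y else "LL" if not hi_x and not hi_y else "HL" if hi_x else "LH"
            )
    return MoranResult(
        I_obs, float(p_global), n_perm, local_I, local_p, clusters,
        float(xv.mean()), float(yv.mean()), n,
    )


# ---------------------------------------------------------------------------
# population centroids and age structure


def population_centroid(grid: PopulationGrid) -> tuple[float, float]:
    """Mass-weighted mean of cell centers."""
    total = grid.total()
    if total <= 0:
        raise ValueError("population grid has zero mass")
    gx, gy = grid.cell_centers()
    return (
        float((grid.values * gx).sum() / total),
        float((grid.values * gy).sum() / total),
    )


def centroid_shift(grid_a: PopulationGrid, grid_b: PopulationGrid) -> tuple[float, float]:
    """Displacement vector from grid A's centroid to grid B's."""
    ax, ay = population_centroid(grid_a)
    bx, by = population_centroid(grid_b)
    return (bx - ax, by - ay)


def age_structure_shares(
    counts: Sequence[tuple[str, float]],
    extra: Sequence[tuple[str, float]] = (),
) -> list[tuple[str, float]]:
    """Percentage shares of age groups, rounded half-up to 2 decimals.

    ``counts`` must partition the population; ``extra`` holds overlapping
    groups (e.g. 65-and-over) computed against the same partition total.
    """
    if any(c < 0 for _, c in list(counts) + list(extra)):
        raise ValueError("counts must be nonnegative")
    total = sum(c for _, c in counts)
    if total <= 0:
        raise ValueError("total population must be positive")
    return [(label, round_half_up(100.0 * c / total, 2)) for label, c in list(counts) + list(extra)]
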