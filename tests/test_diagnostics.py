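"""Diagnostics: KDE against a brute-force oracle, SDE properties and an
eigen-decomposition oracle, bivariate Moran reduction/size, centroids and
age-structure shares."""

from __future__ import annotations

import math

import numpy as np
import pytest

from medaccess import (
    PopulationGrid,
    SpatialWeights,
    age_structure_shares,
    bivariate_moran,
    centroid_shift,
    deviation_ellipse,
    kernel_density,
    population_centroid,
)


def make_grid(extent=(4000.0, 4000.0), cell=200.0) -> PopulationGrid:
    nr, nc = int(extent[1] / cell), int(extent[0] / cell)
    return PopulationGrid((0.0, 0.0), cell, nr, nc, np.zeros((nr, nc)))


# ---------------------------------------------------------------------------
# kernel density


def _kde_bruteforce(points, weights, h, grid, kernel="quartic"):
    """Direct double-loop evaluation of the KDE formula."""
    gx, gy = grid.cell_centers()
    out = np.zeros_like(gx)
    w = np.ones(len(points)) if weights is None else weights
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            total = 0.0
            for (px, py), wi in zip(points, w):
                u = math.hypot(gx[r, c] - px, gy[r, c] - py) / h
                if kernel == "quartic":
                    k = (3.0 / math.pi) * (1 - u * u) ** 2 if u < 1 else 0.0
                else:
                    k = math.exp(-0.5 * u * u) / (2 * math.pi)
                total += wi * k
            out[r, c] = total / h**2
    return out


def test_kde_matches_double_loop_oracle():
    rng = np.random.default_rng(5)
    grid = make_grid()
    pts = rng.uniform(0, 4000, size=(50, 2))
    raster = kernel_density([tuple(p) for p in pts], None, 800.0, grid)
    expected = _kde_bruteforce(pts, None, 800.0, grid)
    assert np.max(np.abs(raster.values - expected)) < 1e-9


def test_kde_gaussian_matches_oracle():
    rng = np.random.default_rng(6)
    grid = make_grid()
    pts = rng.uniform(0, 4000, size=(20, 2))
    w = rng.uniform(0.5, 2.0, size=20)
    raster = kernel_density([tuple(p) for p in pts], w, 600.0, grid, kernel="gaussian")
    expected = _kde_bruteforce(pts, w, 600.0, grid, kernel="gaussian")
    assert np.max(np.abs(raster.values - expected)) < 1e-9


def test_kde_single_point_peaks_at_its_cell_and_decays():
    grid = make_grid()
    raster = kernel_density([(2100.0, 2100.0)], None, 800.0, grid)
    r, c = grid.cell_of(2100.0, 2100.0)
    assert raster.values[r, c] == raster.values.max()
    # monotone decay along the row within the support
    row = raster.values[r, c:]
    inside = row[row > 0]
    assert np.all(np.diff(inside) <= 1e-15)


def test_kde_linearity_two_identical_points():
    grid = make_grid()
    one = kernel_density([(1000.0, 1000.0)], None, 500.0, grid)
    two = kernel_density([(1000.0, 1000.0)] * 2, None, 500.0, grid)
    assert np.allclose(two.values, 2 * one.values, atol=1e-12)


def test_kde_rejects_empty_and_bad_bandwidth():
    grid = make_grid()
    with pytest.raises(ValueError):
        kernel_density([], None, 500.0, grid)
    with pytest.raises(ValueError):
        kernel_density([(0.0, 0.0)], None, 0.0, grid)


# ---------------------------------------------------------------------------
# standard deviational ellipse


def _sde_eigen_oracle(points, weights=None):
    """Principal axes via eigen-decomposition of the weighted covariance."""
    pts = np.asarray(points, float)
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, float)
    mean = (w[:, None] * pts).sum(0) / w.sum()
    d = pts - mean
    cov = (w[:, None, None] * np.einsum("ni,nj->nij", d, d)).sum(0) / w.sum()
    vals, vecs = np.linalg.eigh(cov)
    major = vecs[:, np.argmax(vals)]
    theta = math.degrees(math.atan2(major[0], major[1])) % 180.0
    return mean, math.sqrt(vals.max()), math.sqrt(max(vals.min(), 0.0)), theta


def test_sde_axis_aligned_cross():
    pts = [(1000.0, 0.0), (-1000.0, 0.0), (0.0, 100.0), (0.0, -100.0)]
    e = deviation_ellipse(pts)
    assert e.sigma_x > e.sigma_y
    assert e.theta_deg == pytest.approx(90.0)  # major axis east-west
    assert e.center == pytest.approx((0.0, 0.0))


def test_sde_rotation_equivariance():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(30, 2)) @ np.diag([300.0, 80.0])
    base = deviation_ellipse([tuple(p) for p in pts])
    ang = math.radians(30.0)
    rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    rotated = deviation_ellipse([tuple(p) for p in pts @ rot.T])
    # CCW rotation of the points decreases the clockwise-from-north azimuth
    assert rotated.theta_deg == pytest.approx((base.theta_deg - 30.0) % 180.0, abs=1e-9)
    assert rotated.sigma_x == pytest.approx(base.sigma_x, abs=1e-9)
    assert rotated.sigma_y == pytest.approx(base.sigma_y, abs=1e-9)


def test_sde_translation_invariance():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(25, 2)) * 200.0
    a = deviation_ellipse([tuple(p) for p in pts])
    b = deviation_ellipse([tuple(p) for p in pts + np.array([5000.0, -3000.0])])
    assert b.sigma_x == pytest.approx(a.sigma_x, abs=1e-9)
    assert b.sigma_y == pytest.approx(a.sigma_y, abs=1e-9)
    assert b.theta_deg == pytest.approx(a.theta_deg, abs=1e-9)


def test_sde_matches_eigen_oracle():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(20, 2)) @ np.array([[400.0, 120.0], [0.0, 250.0]])
    w = rng.uniform(1, 5, size=20)
    e = deviation_ellipse([tuple(p) for p in pts], w)
    mean, s_major, s_minor, theta = _sde_eigen_oracle(pts, w)
    assert e.center == pytest.approx(tuple(mean))
    assert e.sigma_x == pytest.approx(s_major, rel=1e-9)
    assert e.sigma_y == pytest.approx(s_minor, rel=1e-9)
    assert e.theta_deg == pytest.approx(theta, abs=1e-9)


def test_sde_degenerate_collinear():
    with pytest.warns(UserWarning):
        e = deviation_ellipse([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
    assert e.degenerate
    assert e.sigma_y == pytest.approx(0.0, abs=1e-9)


def test_sde_needs_two_distinct_points():
    with pytest.raises(ValueError):
        deviation_ellipse([(1.0, 1.0), (1.0, 1.0)])


# ---------------------------------------------------------------------------
# bivariate Moran's I


def _univariate_moran_dense(x, w_dense):
    """Textbook Moran's I with explicit double sum."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    s0 = w_dense.sum()
    num = sum(
        w_dense[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
    )
    return (n / s0) * num / (z @ z)


def test_bivariate_reduces_to_univariate_when_y_equals_x():
    rng = np.random.default_rng(8)
    w = SpatialWeights.rook_grid(4, 4)
    x = rng.normal(size=16)
    res = bivariate_moran(x, x, w, n_perm=99, seed=1)
    expected = _univariate_moran_dense(x, w.standardized().matrix.toarray())
    assert abs(res.I - expected) < 1e-12


def test_clustered_pattern_is_significant():
    # left half high, right half low on a 4x4 grid
    w = SpatialWeights.rook_grid(4, 4)
    x = np.array([1.0, 1.0, 0.0, 0.0] * 4)
    res = bivariate_moran(x, x, w, n_perm=999, seed=2)
    assert res.I > 0
    assert res.p_value <= 0.05


def test_permutation_test_nominal_size_under_independence():
    """Empirical type-I error at alpha = 0.05 within the exact binomial
    99.9% interval over 200 independent replicates."""
    from scipy.stats import binom

    w = SpatialWeights.rook_grid(5, 5)
    rng = np.random.default_rng(42)
    rejections = 0
    n_rep = 200
    for k in range(n_rep):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        res = bivariate_moran(x, y, w, n_perm=199, seed=int(rng.integers(2**31)))
        if res.p_value <= 0.05:
            rejections += 1
    lo = binom.ppf(0.0005, n_rep, 0.05)
    hi = binom.ppf(0.9995, n_rep, 0.05)
    assert lo <= rejections <= hi


def test_zero_variance_rejected():
    w = SpatialWeights.rook_grid(2, 2)
    with pytest.raises(ValueError):
        bivariate_moran([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], w, n_perm=99)


def test_cluster_classes_match_quadrants_where_significant():
    """A smooth high-to-low gradient on an 8x8 grid yields significant HH
    and LL ends, and labels agree with the sign quadrant of (z_x, lag z_y)."""
    w = SpatialWeights.rook_grid(8, 8)
    rng = np.random.default_rng(9)
    base = np.repeat(np.linspace(0, 10, 8), 8).reshape(8, 8).T.ravel()
    x = base + rng.normal(scale=0.3, size=64)
    res = bivariate_moran(x, x, w, n_perm=999, alpha=0.05, seed=3)
    assert "HH" in res.clusters and "LL" in res.clusters
    zx = (x - x.mean()) / x.std()
    lag = w.standardized().matrix @ ((x - x.mean()) / x.std())
    for i, (cls, p) in enumerate(zip(res.clusters, res.local_p)):
        if cls == "not-significant":
            continue
        assert p <= 0.05
        expected = ("H" if zx[i] > 0 else "L") + ("H" if lag[i] > 0 else "L")
        assert cls == expected


# ---------------------------------------------------------------------------
# centroids and age structure


def test_uniform_grid_centroid_at_center():
    grid = PopulationGrid((0.0, 0.0), 1000.0, 4, 4, np.ones((4, 4)))
    assert population_centroid(grid) == pytest.approx((2000.0, 2000.0))


def test_point_mass_centroid_at_cell_center():
    v = np.zeros((3, 3))
    v[2, 1] = 7.0
    grid = PopulationGrid((0.0, 0.0), 1000.0, 3, 3, v)
    assert population_centroid(grid) == pytest.approx((1500.0, 2500.0))


def test_two_cell_weighted_centroid():
    # masses 1 and 3 at centers x = 0 and x = 4000 -> centroid at x = 3000
    grid = PopulationGrid((-2000.0, -2000.0), 4000.0, 1, 2, np.array([[1.0, 3.0]]))
    cx, cy = population_centroid(grid)
    assert cx == pytest.approx(3000.0)
    assert cy == pytest.approx(0.0)


def test_centroid_shift_vector():
    a = PopulationGrid((0.0, 0.0), 1000.0, 2, 2, np.array([[1.0, 0.0], [0.0, 0.0]]))
    b = PopulationGrid((0.0, 0.0), 1000.0, 2, 2, np.array([[0.0, 0.0], [0.0, 1.0]]))
    assert centroid_shift(a, b) == pytest.approx((1000.0, 1000.0))


def test_zero_mass_grid_rejected():
    grid = PopulationGrid((0.0, 0.0), 1000.0, 2, 2, np.zeros((2, 2)))
    with pytest.raises(ValueError):
        population_centroid(grid)


def test_census_age_shares():
    shares = age_structure_shares(
        [("0-14", 1_033_638), ("15-59", 5_928_324), ("60+", 2_108_131)],
        extra=[("65+", 1_403_246)],
    )
    assert dict(shares) == {"0-14": 11.40, "15-59": 65.36, "60+": 23.24, "65+": 15.47}


def test_single_group_is_100_percent():
    assert age_structure_shares([("all", 123)]) == [("all", 100.0)]


def test_negative_count_rejected():
    with pytest.raises(ValueError):
        age_structure_shares([("a", -1), ("b", 2)])
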