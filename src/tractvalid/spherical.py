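"""Sphere sampling grids and real even spherical-harmonic (SH) machinery.

Everything downstream — fiber-response construction, constrained spherical
deconvolution, fODF sampling, and peak extraction — works with the real,
orthonormal, antipodally symmetric (even-order) SH basis defined here.

Conventions
-----------
* Directions are rows of ``(n, 3)`` float arrays with unit Euclidean norm.
* SH coefficient vectors are ordered by ``(l, m)`` with ``l = 0, 2, ..., lmax``
  and ``m = -l ... l`` within each order; ``lmax = 8`` gives 45 coefficients.
* The basis is orthonormal on the sphere, so the SH coefficients of a
  (symmetrized) delta function at ``v`` are simply the basis evaluated at ``v``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import sph_harm_y

__all__ = [
    "fibonacci_sphere",
    "icosphere",
    "SphereGrid",
    "sphere_grid",
    "even_lm",
    "n_coefficients",
    "sh_basis",
    "local_maxima",
    "find_peaks",
    "refine_peaks",
]


# ---------------------------------------------------------------------------
# Point sets
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` approximately equidistant unit vectors (Fibonacci spiral)."""
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return verts, faces


def icosphere(subdivisions: int) -> np.ndarray:
    """Vertices of a subdivided icosahedron (12, 42, 162, 642, 2562, ...)."""
    verts, faces = _icosahedron()
    verts = list(verts)
    cache: dict[tuple[int, int], int] = {}

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in cache:
            m = verts[a] + verts[b]
            m /= np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    for _ in range(subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        faces = np.array(new_faces)
    return np.asarray(verts)


class SphereGrid:
    """A unit-sphere point set with vertex adjacency for local-maximum search."""

    def __init__(self, vertices: np.ndarray):
        self.vertices = np.ascontiguousarray(vertices, dtype=float)
        hull = ConvexHull(self.vertices)
        n = len(self.vertices)
        adj: list[set[int]] = [set() for _ in range(n)]
        for a, b, c in hull.simplices:
            adj[a].update((b, c))
            adj[b].update((a, c))
            adj[c].update((a, b))
        degree = max(len(s) for s in adj)
        # pad ragged neighbor lists with the vertex itself (self-comparisons
        # with >= are harmless for strict local-maximum detection below)
        self.neighbors = np.empty((n, degree), dtype=np.int64)
        for i, s in enumerate(adj):
            row = sorted(s)
            self.neighbors[i] = row + [i] * (degree - len(row))

    def __len__(self) -> int:
        return len(self.vertices)


@lru_cache(maxsize=8)
def sphere_grid(kind: str = "icosphere", level: int = 3) -> SphereGrid:
    """Cached sphere grids. ``icosphere`` levels 2/3 give 162/642 vertices;
    ``fibonacci`` uses ``level`` as the point count (e.g. 8000)."""
    if kind == "icosphere":
        return SphereGrid(icosphere(level))
    if kind == "fibonacci":
        return SphereGrid(fibonacci_sphere(level))
    raise ValueError(f"unknown sphere grid kind: {kind!r}")


# ---------------------------------------------------------------------------
# Real even spherical harmonics
# ---------------------------------------------------------------------------

def even_lm(lmax: int) -> list[tuple[int, int]]:
    """(l, m) index pairs of the even-order real basis, in column order."""
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def n_coefficients(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


def sh_basis(directions: np.ndarray, lmax: int = 8) -> np.ndarray:
    """Evaluate the real even orthonormal SH basis at unit ``directions``.

    Returns an ``(n_dirs, n_coefficients(lmax))`` design matrix.  The real
    basis is built from the complex harmonics ``Y_l^m`` (Condon–Shortley
    phase, scipy convention) as

        m < 0:  sqrt(2) * (-1)^m * Im(Y_l^{|m|})
        m = 0:  Y_l^0
        m > 0:  sqrt(2) * (-1)^m * Re(Y_l^{m})
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    cols = []
    for l, m in even_lm(lmax):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
        elif m == 0:
            cols.append(y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Peak extraction
# ---------------------------------------------------------------------------

def local_maxima(amplitudes: np.ndarray, grid: SphereGrid) -> np.ndarray:
    """Boolean mask of strict-or-equal local maxima over the grid adjacency.

    ``amplitudes`` may be ``(n_vertices,)`` or ``(..., n_vertices)``; the mask
    has the same shape.
    """
    amps = np.asarray(amplitudes)
    neigh = amps[..., grid.neighbors]  # (..., n, degree)
    return amps >= neigh.max(axis=-1)


def _antipodal_canonical(v: np.ndarray) -> np.ndarray:
    """Flip sign so the representative of each axis has non-negative z
    (ties broken on y then x)."""
    v = np.array(v, dtype=float, copy=True)
    flip = (v[..., 2] < 0) | (
        (v[..., 2] == 0) & ((v[..., 1] < 0) | ((v[..., 1] == 0) & (v[..., 0] < 0)))
    )
    v[flip] *= -1.0
    return v


def find_peaks(
    amplitudes: np.ndarray,
    grid: SphereGrid,
    relative_threshold: float = 0.5,
    min_separation_deg: float = 25.0,
    max_peaks: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract up to ``max_peaks`` dominant fODF peak axes from grid samples.

    Peaks are local maxima on the grid whose amplitude exceeds
    ``relative_threshold`` times the global maximum, deduplicated antipodally
    and separated by at least ``min_separation_deg``.  Returns
    ``(directions (k, 3), values (k,))`` sorted by descending amplitude.
    """
    amps = np.asarray(amplitudes, dtype=float)
    peak_mask = local_maxima(amps, grid)
    amax = amps.max()
    if not np.isfinite(amax) or amax <= 0:
        return np.empty((0, 3)), np.empty(0)
    peak_mask &= amps > relative_threshold * amax
    idx = np.flatnonzero(peak_mask)
    if idx.size == 0:
        return np.empty((0, 3)), np.empty(0)
    idx = idx[np.argsort(amps[idx])[::-1]]
    cos_sep = np.cos(np.deg2rad(min_separation_deg))
    dirs: list[np.ndarray] = []
    vals: list[float] = []
    for i in idx:
        v = grid.vertices[i]
        if any(abs(v @ u) > cos_sep for u in dirs):
            continue
        dirs.append(v)
        vals.append(amps[i])
        if len(dirs) >= max_peaks:
            break
    return _antipodal_canonical(np.array(dirs)), np.array(vals)


def _cap_offsets(radius_rad: float, n_azimuth: int = 8) -> np.ndarray:
    """(k, 2) polar offsets (angle from center, azimuth) for cap refinement."""
    offs = [(0.0, 0.0)]
    for r in (radius_rad, 0.5 * radius_rad):
        for a in np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False):
            offs.append((r, a))
    return np.array(offs)


def refine_peaks(
    coefficients: np.ndarray,
    directions: np.ndarray,
    lmax: int = 8,
    radii_deg: tuple[float, ...] = (4.0, 1.6, 0.6, 0.25),
) -> np.ndarray:
    """Refine grid-quantized peak directions by zooming spherical-cap search.

    ``coefficients``: ``(p, n_coef)`` SH coefficients, one row per peak;
    ``directions``: ``(p, 3)`` initial peak axes.  At each stage the SH
    amplitude is evaluated on a small cap of candidate directions around the
    current estimate and the argmax is kept, shrinking the cap radius.
    Returns refined unit axes, antipodally canonicalized.
    """
    coefficients = np.atleast_2d(coefficients)
    dirs = np.atleast_2d(np.asarray(directions, dtype=float)).copy()
    p = len(dirs)
    if p == 0:
        return dirs
    for radius in radii_deg:
        offs = _cap_offsets(np.deg2rad(radius))  # (k, 2)
        # per-peak orthonormal tangent frame
        ref = np.where(np.abs(dirs[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        t1 = np.cross(dirs, ref)
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(dirs, t1)
        ang, az = offs[:, 0], offs[:, 1]
        cand = (
            dirs[:, None, :] * np.cos(ang)[None, :, None]
            + (t1[:, None, :] * np.cos(az)[None, :, None]
               + t2[:, None, :] * np.sin(az)[None, :, None])
            * np.sin(ang)[None, :, None]
        )  # (p, k, 3)
        flat = cand.reshape(-1, 3)
        flat /= np.linalg.norm(flat, axis=1, keepdims=True)
        basis = sh_basis(flat, lmax).reshape(p, len(offs), -1)
        amps = np.einsum("pkc,pc->pk", basis, coefficients)
        best = np.argmax(amps, axis=1)
        dirs = cand[np.arange(p), best]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return _antipodal_canonical(dirs)
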