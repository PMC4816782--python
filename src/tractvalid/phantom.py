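"""Synthetic diffusion-MRI phantoms with known inter-region connections.

The generator emulates a small fixed-tissue HARDI acquisition: a labelled
parcellation of cortical "regions", curved white-matter bundles realizing a
known region-to-region connection matrix, a multi-tensor signal model, and
Rician noise at a configurable SNR.  The rest of the pipeline (CSD, bootstrap
tracking, connection matrices, ROC validation) is exercised against the
phantom's ternary ground truth.

Signal model
------------
Each voxel traversed by one or more bundles holds an equal-fraction mixture of
axially symmetric Gaussian tensor compartments, one per bundle, oriented along
the local centerline tangent.  All other voxels (cortical regions and
background) are isotropic with diffusivity ``d_iso``.  The default
eigenvalues (1.0, 0.18, 0.18) um^2/ms give a single-fiber FA of ~0.80 at
fixed-tissue-like diffusivities; they are free parameters recorded in the
spec, not measurements.

Coordinates: voxel ``(i, j, k)`` has its center at world position
``(i, j, k) * voxel_size`` (mm); bundles are defined in world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .validation import TernaryTruth

__all__ = [
    "GradientScheme",
    "Bundle",
    "PhantomSpec",
    "DwiVolume",
    "PhantomData",
    "GeometryError",
    "make_scheme",
    "build_phantom",
    "six_region_phantom",
    "mixed_length_phantom",
    "straight_bundle_phantom",
    "arc_bundle_phantom",
]

# default tensor eigenvalues (mm^2/s), fixed-tissue-like, FA ~= 0.80
LAMBDA_PARALLEL = 1.0e-3
LAMBDA_PERP = 0.18e-3
D_ISO = 0.35e-3


class GeometryError(ValueError):
    """A bundle centerline leaves the phantom grid."""


# ---------------------------------------------------------------------------
# Gradient schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientScheme:
    """Diffusion sampling directions and b-values defining an acquisition.

    ``directions`` is ``(n, 3)``; rows with ``bvalues > 0`` are unit vectors,
    b=0 rows are zero vectors (FSL convention).
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        b = np.asarray(self.bvalues, dtype=float)
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)
        if d.ndim != 2 or d.shape[1] != 3 or len(d) != len(b):
            raise ValueError("directions must be (n, 3) matching bvalues")
        dw = b > 0
        if not np.any(b == 0):
            raise ValueError("scheme must contain at least one b=0 entry")
        norms = np.linalg.norm(d[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit norm")

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def dw_mask(self) -> np.ndarray:
        return self.bvalues > 0

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0


def make_scheme(
    n_directions: int, bvalue: float, n_b0: int, rng_seed: int = 0
) -> GradientScheme:
    """Build a single-shell scheme with ``n_b0`` b=0 entries prepended and
    ``n_directions`` approximately uniform directions (Fibonacci spiral with a
    seeded random rotation).  The D1 protocol is ``(61, 4000, 7)``; D2 is
    ``(120, 8000, 17)``.
    """
    if n_directions < 6:
        raise ValueError(
            "at least 6 diffusion directions are required (tensor fit is "
            "underdetermined below 6)"
        )
    if n_b0 < 1:
        raise ValueError("n_b0 must be >= 1")
    from .spherical import fibonacci_sphere

    dirs = fibonacci_sphere(n_directions)
    rng = np.random.default_rng(rng_seed)
    # random rotation via QR of a Gaussian matrix (Haar measure)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    dirs = dirs @ q.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvalues = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    return GradientScheme(directions, bvalues)


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bundle:
    """A tube of fibers joining two regions.

    ``control_points`` (m, 3) in world mm define a polyline centerline whose
    endpoints must lie inside the two named regions; ``radius`` is the tube
    radius in mm.
    """

    region_pair: tuple[int, int]
    control_points: np.ndarray
    radius: float


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    voxel_size: float
    regions: dict[int, np.ndarray]  # label -> (k, 3) int voxel indices
    bundles: tuple[Bundle, ...]
    snr: float = np.inf
    rng_seed: int = 0
    s0: float = 1.0
    lambda_parallel: float = LAMBDA_PARALLEL
    lambda_perp: float = LAMBDA_PERP
    d_iso: float = D_ISO
    region_names: dict[int, str] = field(default_factory=dict)

    def validate(self) -> None:
        labels = list(self.regions)
        if any(l <= 0 for l in labels):
            raise ValueError("region labels must be positive integers")
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        seen: set[tuple[int, int, int]] = set()
        shape = np.asarray(self.grid_shape)
        for label, vox in self.regions.items():
            vox = np.asarray(vox)
            if np.any(vox < 0) or np.any(vox >= shape):
                raise GeometryError(f"region {label} leaves the grid")
            for v in map(tuple, vox):
                if v in seen:
                    raise ValueError("region voxel sets must be disjoint")
                seen.add(v)
        for b in self.bundles:
            for label, point in zip(b.region_pair, (b.control_points[0], b.control_points[-1])):
                vox = tuple(np.round(np.asarray(point) / self.voxel_size).astype(int))
                region = {tuple(v) for v in np.asarray(self.regions[label])}
                if vox not in region:
                    raise ValueError(
                        f"bundle endpoint {point} is not inside region {label}"
                    )

    def name_of(self, label: int) -> str:
        return self.region_names.get(label, f"R{label}")


@dataclass(frozen=True)
class DwiVolume:
    """4D diffusion-weighted signal; last axis indexed by the scheme."""

    signal: np.ndarray
    voxel_size: float
    scheme: GradientScheme

    def __post_init__(self):
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError("4th dimension must match the gradient scheme")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")


@dataclass(frozen=True)
class PhantomData:
    """Everything ``build_phantom`` produces.

    ``parcellation`` is an integer label volume (0 = background), ``gm_mask``
    the union of all region voxels, ``truth`` the ternary ground truth over
    region names, and ``bundle_mask`` the voxels any bundle traverses (used as
    the tracking mask: regions + bundles = tissue).
    """

    dwi: DwiVolume
    parcellation: np.ndarray
    gm_mask: np.ndarray
    truth: TernaryTruth
    bundle_mask: np.ndarray
    spec: PhantomSpec

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.gm_mask | self.bundle_mask

    def __iter__(self):
        return iter((self.dwi, self.parcellation, self.gm_mask, self.truth))


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _densify(points: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~``spacing`` and return (samples, unit tangents)."""
    points = np.asarray(points, dtype=float)
    # drop consecutive duplicates (arcs attached to endpoints can repeat them)
    keep = np.concatenate([[True], np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-12])
    points = points[keep]
    segs = np.diff(points, axis=0)
    seg_len = np.linalg.norm(segs, axis=1)
    if len(points) < 2 or np.all(seg_len == 0):
        raise ValueError("degenerate bundle control points")
    samples, tangents = [], []
    for p, d, L in zip(points[:-1], segs, seg_len):
        n = max(int(np.ceil(L / spacing)), 1)
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        samples.append(p + t[:, None] * d)
        tangents.append(np.tile(d / L, (n, 1)))
    samples.append(points[-1:])
    tangents.append(tangents[-1][-1:])
    return np.vstack(samples), np.vstack(tangents)


def _bundle_voxels(
    bundle: Bundle, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxels within the tube radius of the centerline, their tangents, and
    the arc-length-resampled centerline itself."""
    vs = spec.voxel_size
    samples, tangents = _densify(bundle.control_points, vs / 5.0)
    shape = np.asarray(spec.grid_shape)
    vox_samples = samples / vs
    if np.any(vox_samples < -0.5) or np.any(vox_samples > shape - 0.5):
        raise GeometryError("bundle centerline leaves the grid")
    lo = np.maximum(np.floor(vox_samples.min(axis=0) - bundle.radius / vs - 1), 0).astype(int)
    hi = np.minimum(np.ceil(vox_samples.max(axis=0) + bundle.radius / vs + 1), shape - 1).astype(int)
    grid = np.stack(
        np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)], indexing="ij"), -1
    ).reshape(-1, 3)
    centers = grid * vs
    tree = cKDTree(samples)
    dist, idx = tree.query(centers)
    inside = dist <= bundle.radius
    return grid[inside], tangents[idx[inside]], samples


def build_phantom(spec: PhantomSpec, scheme: GradientScheme) -> PhantomData:
    """Simulate the phantom's diffusion signal and assemble its ground truth.

    Per voxel the noise-free signal is an equal-fraction mixture of one
    axially symmetric tensor compartment per traversing bundle (oriented along
    the local centerline tangent); voxels with no bundle are isotropic.
    Rician noise is applied at ``spec.snr`` (defined on the b=0 signal) using
    ``spec.rng_seed``; ``snr = inf`` is noise-free and bit-reproducible.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    nvol = len(scheme)
    b = scheme.bvalues
    g = scheme.directions

    # start fully isotropic
    iso = spec.s0 * np.exp(-b * spec.d_iso)
    iso[scheme.b0_mask] = spec.s0
    signal = np.broadcast_to(iso, shape + (nvol,)).copy()

    # accumulate tensor compartments per voxel
    comp_sum: dict[tuple[int, int, int], list[np.ndarray]] = {}
    bundle_mask = np.zeros(shape, dtype=bool)
    dl = spec.lambda_parallel - spec.lambda_perp
    for bundle in spec.bundles:
        voxels, tangents, _ = _bundle_voxels(bundle, spec)
        att = np.exp(-b * (spec.lambda_perp + dl * (tangents @ g.T) ** 2))
        att[:, scheme.b0_mask] = 1.0
        for vox, a in zip(map(tuple, voxels), att):
            comp_sum.setdefault(vox, []).append(spec.s0 * a)
        bundle_mask[tuple(voxels.T)] = True
    for vox, comps in comp_sum.items():
        signal[vox] = np.mean(comps, axis=0)

    if np.isfinite(spec.snr):
        if spec.snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(spec.rng_seed)
        sigma = spec.s0 / spec.snr
        noise = rng.normal(scale=sigma, size=signal.shape + (2,))
        signal = np.sqrt((signal + noise[..., 0]) ** 2 + noise[..., 1] ** 2)

    parcellation = np.zeros(shape, dtype=np.int32)
    gm_mask = np.zeros(shape, dtype=bool)
    for label, vox in spec.regions.items():
        vox = np.asarray(vox)
        parcellation[tuple(vox.T)] = label
        gm_mask[tuple(vox.T)] = True

    labels = sorted(spec.regions)
    names = [spec.name_of(l) for l in labels]
    n = len(labels)
    states = np.zeros((n, n), dtype=int)
    np.fill_diagonal(states, -1)
    index = {l: i for i, l in enumerate(labels)}
    for bundle in spec.bundles:
        i, j = index[bundle.region_pair[0]], index[bundle.region_pair[1]]
        states[i, j] = states[j, i] = 1
    truth = TernaryTruth(states, names)

    dwi = DwiVolume(signal, spec.voxel_size, scheme)
    return PhantomData(dwi, parcellation, gm_mask, truth, bundle_mask, spec)


# ---------------------------------------------------------------------------
# Stated-world factories
# ---------------------------------------------------------------------------

def _block(center: tuple[int, int, int], half: int | tuple[int, int, int] = 1) -> np.ndarray:
    """A box of voxel indices around ``center`` with per-axis half-widths."""
    hx, hy, hz = (half, half, half) if np.isscalar(half) else half
    return np.array([(center[0] + i, center[1] + j, center[2] + k)
                     for i in range(-hx, hx + 1)
                     for j in range(-hy, hy + 1)
                     for k in range(-hz, hz + 1)])


def _arc(p0: np.ndarray, p1: np.ndarray, sagitta: float, n: int = 33,
         normal: tuple[float, float, float] = (0.0, 0.0, 1.0)) -> np.ndarray:
    """Planar circular-ish arc from p0 to p1 bulging by ``sagitta`` mm."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    chord = p1 - p0
    side = np.cross(normal, chord)
    side /= np.linalg.norm(side)
    t = np.linspace(0.0, 1.0, n)
    return p0 + t[:, None] * chord + (np.sin(np.pi * t) * sagitta)[:, None] * side


def six_region_phantom(snr: float = 20.0, rng_seed: int = 0) -> PhantomSpec:
    """Six regions and five recoverable bundles (one curved), SNR 20 default.

    Probabilistic streamlines pass through shared regions, so the topology is
    chosen to keep such transits off the absent pairs: regions 1-2-3 form a
    fully connected triangle (a transit across any corner lands on a pair
    that is itself connected), and the 4-5-6 path has an elongated hub
    (region 5) whose two tube mouths are separated by several isotropic
    gray-matter voxels, suppressing transit between regions 4 and 6.  All
    bundles are < 20 voxels long and reliably tracked at SNR 20.
    """
    vs = 1.0
    z = 5
    centers = {1: (6, 6, z), 2: (16, 6, z), 3: (11, 16, z),
               4: (27, 5, z), 5: (27, 16, z), 6: (27, 27, z)}
    halves = {1: 1, 2: 1, 3: 1, 4: 1, 5: (1, 4, 1), 6: 1}
    regions = {l: _block(c, halves[l]) for l, c in centers.items()}

    def w(label, offset=(0, 0, 0)):
        return (np.asarray(centers[label], float) + offset) * vs

    bundles = (
        Bundle((1, 2), np.array([w(1, (1, 0, 0)), w(2, (-1, 0, 0))]), 1.1),
        Bundle((2, 3), np.array([w(2, (-1, 1, 0)), w(3, (1, -1, 0))]), 1.1),
        Bundle((1, 3), _arc(w(1, (0, 1, 0)), w(3, (-1, 0, 0)), sagitta=-3.0), 1.1),
        Bundle((4, 5), np.array([w(4, (0, 1, 0)), w(5, (0, -4, 0))]), 1.1),
        Bundle((5, 6), np.array([w(5, (0, 4, 0)), w(6, (0, -1, 0))]), 1.1),
    )
    return PhantomSpec(
        grid_shape=(33, 33, 11), voxel_size=vs, regions=regions,
        bundles=bundles, snr=snr, rng_seed=rng_seed,
    )


def mixed_length_phantom(snr: float = 20.0, rng_seed: int = 0) -> PhantomSpec:
    """Six regions, five bundles with strongly mixed lengths (~6 to ~37 mm).

    Built to exhibit the distance effect of probabilistic tracking: the
    longest bundle is thin, long, and curved, so its uncorrected connection
    strength decays well below the short bundles'.  The same transit-safe
    topology as :func:`six_region_phantom` is used (triangle plus hardened
    hub).
    """
    vs = 1.0
    z = 5
    centers = {1: (6, 6, z), 2: (13, 6, z), 3: (9, 15, z),
               4: (27, 4, z), 5: (27, 11, z), 6: (15, 34, z)}
    halves = {1: 1, 2: 1, 3: 1, 4: 1, 5: (1, 3, 1), 6: 1}
    regions = {l: _block(c, halves[l]) for l, c in centers.items()}

    def w(label, offset=(0, 0, 0)):
        return (np.asarray(centers[label], float) + offset) * vs

    bundles = (
        Bundle((1, 2), np.array([w(1, (1, 0, 0)), w(2, (-1, 0, 0))]), 1.1),   # ~5 mm
        Bundle((2, 3), np.array([w(2, (-1, 1, 0)), w(3, (1, -1, 0))]), 1.1),  # ~8 mm
        Bundle((1, 3), _arc(w(1, (1, 1, 0)), w(3, (-1, -1, 0)), sagitta=3.0), 1.1),  # ~11 mm
        Bundle((4, 5), np.array([w(4, (0, 1, 0)), w(5, (0, -3, 0))]), 1.1),   # ~4 mm
        # long, thin, curved: hub 5 north end to region 6 the long way round;
        # its strength decays well below the short bundles' (distance effect)
        Bundle((5, 6), _arc(w(5, (0, 3, 0)), w(6, (0, 1, 0)), sagitta=-12.0), 0.75),  # ~40 mm
    )
    return PhantomSpec(
        grid_shape=(34, 40, 11), voxel_size=vs, regions=regions,
        bundles=bundles, snr=snr, rng_seed=rng_seed,
    )


def straight_bundle_phantom(
    length_mm: float = 10.0, snr: float = np.inf, rng_seed: int = 0
) -> PhantomSpec:
    """Two single-voxel regions joined by one straight bundle along x.

    The tube fully covers both seed voxels, so arrival statistics measure
    propagation fidelity rather than seed placement."""
    vs = 1.0
    z = 4
    n = int(np.ceil(length_mm)) + 8
    c1, c2 = (3, 4, z), (3 + int(length_mm), 4, z)
    regions = {1: _block(c1, half=0), 2: _block(c2, half=0)}
    bundles = (
        Bundle((1, 2), np.array([np.asarray(c1, float) * vs,
                                 np.asarray(c2, float) * vs]), 1.1),
    )
    return PhantomSpec(
        grid_shape=(n, 9, 9), voxel_size=vs, regions=regions,
        bundles=bundles, snr=snr, rng_seed=rng_seed,
    )


def arc_bundle_phantom(
    radius_mm: float = 1.3, snr: float = 20.0, rng_seed: int = 0
) -> PhantomSpec:
    """Two regions joined by a tight half-circle arc (high curvature per step).

    With ``radius_mm = 1.3`` the nominal turning is ~44 degrees per 1 mm step,
    so per-step curvature beyond 70 degrees occurs once orientation dispersion
    is added — used to exercise curvature-threshold termination.
    """
    vs = 1.0
    z = 4
    c1, c2 = (4, 4, z), (4 + int(round(2 * radius_mm)), 4, z)
    regions = {1: _block(c1, half=0), 2: _block(c2, half=0)}
    mid = (np.asarray(c1, float) + np.asarray(c2, float)) / 2.0 * vs
    theta = np.linspace(np.pi, 0.0, 41)
    arc = np.column_stack([
        mid[0] + radius_mm * np.cos(theta),
        mid[1] + radius_mm * np.sin(theta),
        np.full_like(theta, z * vs),
    ])
    pts = np.vstack([np.asarray(c1, float) * vs, arc, np.asarray(c2, float) * vs])
    bundles = (Bundle((1, 2), pts, 1.1),)
    return PhantomSpec(
        grid_shape=(9 + int(round(2 * radius_mm)), 9 + int(np.ceil(radius_mm)), 9),
        voxel_size=vs, regions=regions, bundles=bundles, snr=snr, rng_seed=rng_seed,
    )
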