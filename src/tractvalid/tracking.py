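"""Residual-bootstrap orientation PDFs and Monte Carlo streamline tracking.

Orientation uncertainty is estimated per voxel by model-based residual
bootstrapping of the CSD fit: the diffusion-weighted residuals against the
fitted fODF's signal prediction are resampled with replacement, added back to
the prediction, and the fODF is refit; the peak axes of each replicate form
the voxel's orientation PDF (a sample set, not a parametric density).

Streamlines are propagated bidirectionally from seed voxel centers.  At each
step one bootstrap replicate of the current voxel (nearest-voxel lookup) is
drawn at random; among its peak axes, the one most aligned with the incoming
direction is taken (sign-aligned, ties to the first index).  A step is
rejected — terminating the streamline — when the turning angle exceeds the
curvature threshold, when FA at the entered voxel falls below the FA
threshold (outside the gray-matter mask when the exemption is active,
everywhere otherwise), when the path leaves the volume or the tracking mask,
or after ``max_steps``.  Replicates with no detectable peak mark the voxel
draw as isotropic and fall back to a uniformly random axis.

All random draws for a streamline are pre-generated per (streamline, sense,
step), so a run is reproducible for a fixed seed and tightening a
constraint can only truncate — never redirect — a given streamline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spherical
from .fodf import LMAX, CsdDeconvolver, ResponseFunction
from .phantom import DwiVolume, GradientScheme

__all__ = [
    "TrackingConfig",
    "Streamline",
    "PdfField",
    "bootstrap_pdf",
    "bootstrap_pdf_field",
    "propagate",
    "track_region",
    "fa_volume",
]

MAX_PEAKS = 3


@dataclass(frozen=True)
class TrackingConfig:
    """Propagation parameters.

    ``step_size = None`` resolves to half the voxel size at tracking time.
    ``curvature_threshold`` is the maximum turning angle per step in degrees
    (180 disables the constraint; after sign alignment turning never exceeds
    90, so thresholds >= 90 reject nothing).  ``fa_threshold = 0`` disables FA
    termination since FA is non-negative.
    """

    streamlines_per_voxel: int = 1000
    step_size: float | None = None
    curvature_threshold: float | None = 180.0  # None = constraint disabled
    fa_threshold: float = 0.0
    gm_mask_exempt: bool = True
    max_steps: int = 300
    rng_seed: int = 0

    def __post_init__(self):
        if self.streamlines_per_voxel < 1:
            raise ValueError("streamlines_per_voxel must be >= 1")
        if not 0.0 <= self.fa_threshold < 1.0:
            raise ValueError("fa_threshold must be in [0, 1)")
        if self.curvature_threshold is not None \
                and not 0.0 < self.curvature_threshold <= 180.0:
            raise ValueError("curvature_threshold must be in (0, 180] or None")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")

    def resolve_step(self, voxel_size: float) -> float:
        step = 0.5 * voxel_size if self.step_size is None else self.step_size
        if step > voxel_size + 1e-9:
            raise ValueError("step_size must not exceed the voxel size")
        return step


@dataclass(frozen=True)
class Streamline:
    """An ordered 3D point sequence (mm) produced by bidirectional tracking.

    ``termination_reasons`` holds the (backward, forward) end reasons; the
    spec-level single ``termination_reason`` is the forward one.
    """

    points: np.ndarray
    seed_region: int
    termination_reasons: tuple[str, str]
    seed_index: int = 0       # which seed voxel of the region launched it
    seed_point_index: int = 0  # index of the seed point within ``points``

    @property
    def termination_reason(self) -> str:
        return self.termination_reasons[1]

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class PdfField:
    """Per-voxel orientation PDFs as bootstrap peak-sample tables.

    ``peaks``: (n_mask_voxels, n_boot, MAX_PEAKS, 3) unit axes (NaN padded);
    ``n_peaks``: (n_mask_voxels, n_boot) peak counts (0 = isotropic draw);
    ``index``: int volume mapping voxel -> table row (-1 outside the mask).
    """

    peaks: np.ndarray
    n_peaks: np.ndarray
    index: np.ndarray
    n_boot: int
    voxel_size: float
    isotropic_fraction: float = field(default=0.0)


# ---------------------------------------------------------------------------
# Bootstrap PDFs
# ---------------------------------------------------------------------------

def _batch_peaks(
    coeffs: np.ndarray,
    relative_threshold: float = 0.5,
    min_separation_deg: float = 25.0,
    max_peaks: int = MAX_PEAKS,
    grid_level: int = 3,
    chunk: int = 4000,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak axes for many coefficient vectors at once.

    Returns ``(peaks (n, max_peaks, 3) NaN-padded, counts (n,))``.  Coarse
    local maxima on the level-3 icosphere are refined off-grid in one batched
    pass.
    """
    coeffs = np.atleast_2d(coeffs)
    n = len(coeffs)
    grid = spherical.sphere_grid("icosphere", grid_level)
    basis = spherical.sh_basis(grid.vertices, LMAX)
    out = np.full((n, max_peaks, 3), np.nan)
    counts = np.zeros(n, dtype=np.uint8)
    cos_sep = np.cos(np.deg2rad(min_separation_deg))
    pending_c, pending_d, pending_at = [], [], []
    for start in range(0, n, chunk):
        block = coeffs[start : start + chunk]
        amps = block @ basis.T
        is_max = spherical.local_maxima(amps, grid)
        mx = amps.max(axis=1)
        cand = is_max & (amps > relative_threshold * np.maximum(mx, 0.0)[:, None]) & (mx > 0)[:, None]
        for i in np.flatnonzero(cand.any(axis=1)):
            idx = np.flatnonzero(cand[i])
            idx = idx[np.argsort(amps[i, idx])[::-1]]
            dirs: list[np.ndarray] = []
            for q in idx:
                v = grid.vertices[q]
                if any(abs(v @ u) > cos_sep for u in dirs):
                    continue
                dirs.append(v)
                if len(dirs) >= max_peaks:
                    break
            pending_c.append(np.tile(coeffs[start + i], (len(dirs), 1)))
            pending_d.append(np.array(dirs))
            pending_at.append(np.full(len(dirs), start + i))
            counts[start + i] = len(dirs)
    if pending_c:
        refined = spherical.refine_peaks(np.vstack(pending_c), np.vstack(pending_d), LMAX)
        at = np.concatenate(pending_at)
        slot = np.concatenate([np.arange(c) for c in counts[counts > 0]])
        out[at, slot] = refined
    return out, counts


def bootstrap_pdf(
    signals: np.ndarray,
    scheme: GradientScheme,
    response: ResponseFunction,
    n_boot: int,
    rng_seed: int = 0,
    deconvolver: CsdDeconvolver | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Residual-bootstrap orientation PDF for a single voxel.

    Returns ``(peaks (n_boot, MAX_PEAKS, 3) NaN-padded, counts (n_boot,))``.
    Replicates whose fODF has no detectable peak get count 0 (isotropic).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if deconvolver is None:
        deconvolver = CsdDeconvolver(scheme, response, enforce_nonneg=False)
    signals = np.asarray(signals, dtype=float)
    reps = _bootstrap_signals(signals[None], deconvolver, n_boot,
                              np.random.default_rng(rng_seed))
    coeffs, _ = deconvolver.fit_batch(reps.reshape(n_boot, -1))
    peaks, counts = _batch_peaks(coeffs)
    return peaks, counts


def _bootstrap_signals(
    signals: np.ndarray, dec: CsdDeconvolver, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """(V, n_boot, n_meas) bootstrap replicate signals (b=0 entries fixed).

    The model prediction is the plain lmax-8 spherical-harmonic fit of the
    normalized DW signal (the standard model for residual bootstrapping of
    spherical-deconvolution pipelines); its per-direction residuals, rescaled
    by the leverage correction 1/sqrt(1 - h_ii) to undo the fit's shrinkage
    of the noise, are resampled with replacement and added back.  Noise-free
    data yields near-zero residuals regardless of the CSD regularization."""
    scheme = dec.scheme
    V = len(signals)
    s0 = signals[:, scheme.b0_mask].mean(axis=1, keepdims=True)
    s0 = np.where(s0 > 0, s0, 1.0)
    s_norm = signals[:, scheme.dw_mask] / s0
    basis = spherical.sh_basis(scheme.directions[scheme.dw_mask], dec.lmax)
    pinv = np.linalg.pinv(basis)
    pred = (s_norm @ pinv.T) @ basis.T
    leverage = np.einsum("ij,ji->i", basis, pinv)
    resid = (s_norm - pred) / np.sqrt(np.clip(1.0 - leverage, 1e-3, None))
    ndw = resid.shape[1]
    idx = rng.integers(0, ndw, size=(V, n_boot, ndw))
    boot_dw = pred[:, None, :] + np.take_along_axis(
        resid[:, None, :], idx, axis=2
    )
    reps = np.empty((V, n_boot, signals.shape[1]))
    reps[:, :, scheme.b0_mask] = (signals[:, scheme.b0_mask])[:, None, :]
    reps[:, :, scheme.dw_mask] = np.clip(boot_dw, 0.0, None) * s0[:, None, :]
    return reps


def bootstrap_pdf_field(
    dwi: DwiVolume,
    mask: np.ndarray,
    response: ResponseFunction,
    n_boot: int = 50,
    rng_seed: int = 0,
    chunk: int = 250,
    deconvolver: CsdDeconvolver | None = None,
) -> PdfField:
    """Bootstrap orientation PDFs for every voxel of a boolean mask."""
    if deconvolver is None:
        deconvolver = CsdDeconvolver(dwi.scheme, response, enforce_nonneg=False)
    flat_idx = np.flatnonzero(mask)
    vox_signals = dwi.signal.reshape(-1, dwi.signal.shape[-1])[flat_idx]
    V = len(flat_idx)
    rng = np.random.default_rng(rng_seed)
    peaks = np.full((V, n_boot, MAX_PEAKS, 3), np.nan, dtype=np.float32)
    counts = np.zeros((V, n_boot), dtype=np.uint8)
    for start in range(0, V, chunk):
        sig = vox_signals[start : start + chunk]
        reps = _bootstrap_signals(sig, deconvolver, n_boot, rng)
        coeffs, _ = deconvolver.fit_batch(reps.reshape(-1, reps.shape[-1]))
        p, c = _batch_peaks(coeffs)
        peaks[start : start + chunk] = p.reshape(len(sig), n_boot, MAX_PEAKS, 3)
        counts[start : start + chunk] = c.reshape(len(sig), n_boot)
    index = np.full(mask.shape, -1, dtype=np.int64)
    index.reshape(-1)[flat_idx] = np.arange(V)
    return PdfField(peaks, counts, index, n_boot, dwi.voxel_size,
                    float((counts == 0).mean()))


def fa_volume(dwi: DwiVolume, mask: np.ndarray | None = None) -> np.ndarray:
    """FA map from the log-linear tensor fit (0 outside the mask)."""
    from .fodf import fit_tensor_batch

    if mask is None:
        mask = np.ones(dwi.signal.shape[:3], dtype=bool)
    flat = np.flatnonzero(mask)
    sig = dwi.signal.reshape(-1, dwi.signal.shape[-1])[flat]
    fa, _, _ = fit_tensor_batch(sig, dwi.scheme)
    out = np.zeros(mask.shape)
    out.reshape(-1)[flat] = fa
    return out


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(n > 0, n, 1.0)


class _BatchTracker:
    """Vectorized bidirectional propagation of a batch of streamlines."""

    def __init__(self, pdf: PdfField, fa_map, gm_mask, config: TrackingConfig,
                 tracking_mask=None):
        self.pdf = pdf
        self.fa = np.asarray(fa_map)
        self.gm = np.asarray(gm_mask, dtype=bool)
        self.cfg = config
        self.mask = tracking_mask
        self.vs = pdf.voxel_size
        self.step = config.resolve_step(self.vs)
        self.shape = np.array(pdf.index.shape)
        self.cos_limit = (-2.0 if config.curvature_threshold is None
                          else np.cos(np.deg2rad(config.curvature_threshold)))

    def _voxels(self, pos: np.ndarray) -> np.ndarray:
        return np.rint(pos / self.vs).astype(np.int64)

    def _inside(self, vox: np.ndarray) -> np.ndarray:
        return np.all((vox >= 0) & (vox < self.shape), axis=-1)

    def run(self, seeds: np.ndarray, rng: np.random.Generator):
        """Track one streamline per seed point (mm).  Returns per-seed point
        arrays for both senses plus termination reasons."""
        n = len(seeds)
        cfg = self.cfg
        vox0 = self._voxels(seeds)
        if not np.all(self._inside(vox0)):
            raise ValueError("seed point outside the volume")
        # pre-generated randomness: one PDF sample + peak choice + fallback
        # axis per (streamline, sense, step); step 0 of sense 1 reuses the
        # initial orientation of sense 0 with opposite sign.
        samp = rng.integers(0, self.pdf.n_boot, size=(n, 2, cfg.max_steps))
        peak_u = rng.random(size=(n, 2, cfg.max_steps))
        gauss = rng.standard_normal(size=(n, 2, cfg.max_steps, 3)).astype(np.float32)

        points = [np.zeros((n, 0, 3)), np.zeros((n, 0, 3))]
        reasons = np.empty((n, 2), dtype=object)
        init_dir = self._draw(vox0, samp[:, 0, 0], peak_u[:, 0, 0],
                              gauss[:, 0, 0], incoming=None)
        for sense in (0, 1):
            sign = 1.0 if sense == 0 else -1.0
            pos = seeds.astype(float).copy()
            direction = sign * init_dir.copy()
            active = np.ones(n, dtype=bool)
            reason = np.full(n, "max-steps", dtype=object)
            buf = np.full((n, cfg.max_steps, 3), np.nan, dtype=np.float32)
            n_pts = np.zeros(n, dtype=np.int64)
            for step_i in range(cfg.max_steps):
                idx = np.flatnonzero(active)
                if idx.size == 0:
                    break
                vox = self._voxels(pos[idx])
                if step_i > 0:
                    drawn = self._draw(
                        vox, samp[idx, sense, step_i], peak_u[idx, sense, step_i],
                        gauss[idx, sense, step_i], incoming=direction[idx],
                    )
                    cosang = np.einsum("ij,ij->i", drawn, direction[idx])
                    # reject the step if turning exceeds the threshold
                    bad = cosang < self.cos_limit - 1e-12
                    if np.any(bad):
                        reason[idx[bad]] = "curvature"
                        active[idx[bad]] = False
                        idx = idx[~bad]
                        drawn = drawn[~bad]
                    direction[idx] = drawn
                new_pos = pos[idx] + self.step * direction[idx]
                new_vox = self._voxels(new_pos)
                inside = self._inside(new_vox)
                if np.any(~inside):
                    reason[idx[~inside]] = "left-volume"
                    active[idx[~inside]] = False
                    idx, new_pos, new_vox = idx[inside], new_pos[inside], new_vox[inside]
                if self.mask is not None and idx.size:
                    ok = self.mask[tuple(new_vox.T)]
                    if np.any(~ok):
                        reason[idx[~ok]] = "mask-exit"
                        active[idx[~ok]] = False
                        idx, new_pos, new_vox = idx[ok], new_pos[ok], new_vox[ok]
                if cfg.fa_threshold > 0 and idx.size:
                    low = self.fa[tuple(new_vox.T)] < cfg.fa_threshold
                    if cfg.gm_mask_exempt:
                        low &= ~self.gm[tuple(new_vox.T)]
                    if np.any(low):
                        reason[idx[low]] = "fa"
                        active[idx[low]] = False
                        idx, new_pos = idx[~low], new_pos[~low]
                if idx.size:
                    pos[idx] = new_pos
                    buf[idx, n_pts[idx]] = new_pos
                    n_pts[idx] += 1
            points[sense] = buf
            reasons[:, sense] = reason
            if sense == 0:
                n_pts0 = n_pts
            else:
                n_pts1 = n_pts
        return points, (n_pts0, n_pts1), reasons

    def _draw(self, vox, samp_idx, peak_u, gauss, incoming):
        """Draw one orientation per streamline from the voxel PDFs."""
        rows = self.pdf.index[tuple(vox.T)]
        # rows are guaranteed >= 0 while tracking stays inside the PDF mask;
        # outside it (no tracking mask configured) fall back to isotropic.
        valid = rows >= 0
        k = np.zeros(len(vox), dtype=np.int64)
        k[valid] = self.pdf.n_peaks[rows[valid], samp_idx[valid]]
        out = _unit(gauss.astype(float))  # isotropic fallback
        has = valid & (k > 0)
        if np.any(has):
            cand = self.pdf.peaks[rows[has], samp_idx[has]].astype(float)  # (m, K, 3)
            kk = k[has]
            if incoming is None:
                choice = np.minimum((peak_u[has] * kk).astype(np.int64), kk - 1)
                out[has] = cand[np.arange(len(kk)), choice]
            else:
                dots = np.einsum("mkj,mj->mk", np.nan_to_num(cand), incoming[has])
                slot = np.arange(cand.shape[1])[None, :] >= kk[:, None]
                adots = np.where(slot, -1.0, np.abs(dots))
                choice = np.argmax(adots, axis=1)
                m = np.arange(len(kk))
                out[has] = cand[m, choice] * np.sign(dots[m, choice])[:, None]
        if incoming is not None:
            flip = np.einsum("ij,ij->i", out, incoming) < 0
            out[flip] *= -1.0
        return _unit(out)


def propagate(
    seed_point: np.ndarray,
    pdf_field: PdfField,
    fa_map: np.ndarray,
    gm_mask: np.ndarray,
    config: TrackingConfig,
    rng: np.random.Generator | int | None = None,
    tracking_mask: np.ndarray | None = None,
    seed_region: int = 0,
) -> Streamline:
    """Propagate a single bidirectional streamline from ``seed_point`` (mm)."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng if rng is not None else config.rng_seed)
    tracker = _BatchTracker(pdf_field, fa_map, gm_mask, config, tracking_mask)
    pts, counts, reasons = tracker.run(np.atleast_2d(np.asarray(seed_point, float)), rng)
    return _assemble(0, np.atleast_2d(seed_point), pts, counts, reasons,
                     seed_region, 0)


def _assemble(i, seeds, pts, counts, reasons, seed_region, seed_index) -> Streamline:
    n0, n1 = counts[0][i], counts[1][i]
    back = pts[1][i, :n1][::-1]
    fwd = pts[0][i, :n0]
    full = np.vstack([back, seeds[i][None].astype(np.float32), fwd])
    return Streamline(full, seed_region, (str(reasons[i, 1]), str(reasons[i, 0])),
                      seed_index, int(n1))


def track_region(
    region_label: int,
    parcellation: np.ndarray,
    pdf_field: PdfField,
    fa_map: np.ndarray,
    gm_mask: np.ndarray,
    config: TrackingConfig,
    tracking_mask: np.ndarray | None = None,
) -> list[Streamline]:
    """Launch ``config.streamlines_per_voxel`` streamlines from the center of
    every voxel of a seed region.  Deterministic for a fixed
    ``config.rng_seed`` (the seed is combined with the region label so
    different regions draw independent streams)."""
    vox = np.argwhere(np.asarray(parcellation) == region_label)
    if len(vox) == 0:
        raise ValueError(f"region {region_label} is empty")
    seeds = np.repeat(vox * pdf_field.voxel_size, config.streamlines_per_voxel, axis=0)
    seed_ids = np.repeat(np.arange(len(vox)), config.streamlines_per_voxel)
    tracker = _BatchTracker(pdf_field, fa_map, gm_mask, config, tracking_mask)
    out: list[Streamline] = []
    # fixed-size chunks with independently seeded streams keep results
    # deterministic and memory bounded regardless of the total seed count
    chunk = 8192
    for ci, start in enumerate(range(0, len(seeds), chunk)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.rng_seed,
                                   spawn_key=(int(region_label), ci))
        )
        sub = seeds[start : start + chunk].astype(float)
        pts, counts, reasons = tracker.run(sub, rng)
        out.extend(
            _assemble(i, sub, pts, counts, reasons, region_label,
                      int(seed_ids[start + i]))
            for i in range(len(sub))
        )
    return out
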