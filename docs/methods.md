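# Methods

`tractvalid` implements a full desk-scale replica of a tractography-validation
experiment: probabilistic streamline tractography is run between cortical
regions, the resulting connection matrices are compared against a ternary
(present / absent / indeterminate) ground truth, and the influence of
acceptance thresholds, distance corrections, and curvature/FA termination
constraints is quantified. Because the original postmortem macaque scans are
not deposited anywhere, the pipeline is exercised on synthetic phantoms with
known connections; the tracer-atlas fragments that *are* pinned down in print
(the false-connection tables and the region-name mapping) ship as packaged
fixtures.

## Phantom model

Each phantom is a voxel grid (voxel `(i,j,k)` centered at world
`(i,j,k) * voxel_size` mm) containing labelled gray-matter regions and
white-matter bundles. A bundle is a tube of radius `r` around a polyline
centerline whose endpoints lie inside its two regions. The noise-free signal
is a Gaussian multi-tensor:

* voxels traversed by bundles hold an equal-fraction mixture of axially
  symmetric tensor compartments, one per bundle, oriented along the local
  centerline tangent, with eigenvalues `(1.0, 0.18, 0.18) um^2/ms`
  (single-fiber FA 0.80 — fixed-tissue-like diffusivities, a free design
  choice recorded in the phantom configuration, not a measurement);
* all other voxels (cortical regions and background) are isotropic with
  `D_iso = 0.35e-3 mm^2/s`.

Rician noise is applied at a configurable SNR defined on the b=0 signal
(`sigma = S0/SNR`); `SNR = inf` is exactly noise-free and bit-reproducible.
The default acquisition replays the 61-direction single-shell scheme at
b = 4000 s/mm^2 with 7 b=0 volumes; a 120-direction b = 8000 scheme is also
available. Directions are a Fibonacci spiral under a seeded random rotation.

Two stated-world layouts matter:

* **six_region** — five bundles (< 20 voxels, one curved) over six regions at
  SNR 20. Probabilistic streamlines pass *through* shared regions and would
  otherwise bridge unconnected pairs, so the topology is transit-safe:
  regions 1–3 form a fully connected triangle (a corner transit lands on a
  pair that is itself connected) and the 4–5–6 path has an elongated hub
  whose two tube mouths are separated by several isotropic voxels. With this
  layout the weakest bundle scores ~12–14% of initiated streamlines while the
  strongest spurious pair stays below ~0.5%, so a threshold scan reaches 100%
  accuracy with margin.
* **mixed_length** — bundle lengths ~5/8/11/4/40 mm; the longest is thin
  (radius 0.75 voxels) and curved so that its strength decays to well under
  1%. This is the world in which the distance bias of probabilistic
  tractography, and its partial repair by length corrections, is visible.

What the phantoms do **not** emulate: fixation effects, coil profiles, EPI
distortion, partial-volume mixtures at tube boundaries (bundle voxels are
pure tensor mixtures), crossing-rich white matter, and gyral geometry. A
green end-to-end test therefore establishes that the pipeline's machinery is
correct and self-consistent — not that real-tissue accuracy would match.

## Preprocessing

Optional slice-wise 2D Perona–Malik anisotropic diffusion smoothing
(exponential conductance, explicit flux-form update, Neumann boundaries, so
the slice sum is conserved to float precision). Only the iteration count (5)
has an established default; `kappa` defaults to 10% of each slice's dynamic
range and the time step to 0.2 (stability bound 0.25). Smoothing is off by
default — it exists for low-SNR inputs.

## Fiber orientation estimation

* **Tensor / FA**: standard log-linear least squares on `ln S`; FA from the
  eigenvalues by the normalized-variance formula. Used for FA maps and as
  the analytic oracle on single-fiber voxels.
* **Single-fiber response**: an axially symmetric tensor with FA 0.8 at the
  acquisition b-value (mean diffusivity defaulting to the phantom tensor's
  trace/3), projected onto even zonal harmonics up to `lmax = 8` by
  Gauss–Legendre quadrature.
* **CSD**: iterative Tikhonov-regularized spherical deconvolution in a real,
  orthonormal, even-order SH basis (45 coefficients). Per iteration, sampled
  amplitudes below `tau = 0.1 x` the mean initial-fODF amplitude (on a
  321-axis icosphere hemisphere) are penalized with weight `lambda = 1`
  (constraint rows rescaled to the RMS row norm of the forward matrix so
  `lambda` is dimensionless); convergence = stable constrained set, cap 50
  iterations (non-convergence returns the last iterate with a warning).
* **Non-negativity projection**: the soft penalty cannot push residual
  negative lobes below ~5e-3 of the maximum (with more active constraints
  than degrees of freedom the penalized optimum keeps small negatives), so a
  final Douglas–Rachford projection between the SH subspace and the cone of
  non-negative amplitudes on the dense sample set brings every voxel to
  `min amplitude >= -1e-4 x max`. Peak geometry is unaffected (only
  near-zero lobes are reshaped). Bootstrap replicate refits skip this stage
  for speed; peak extraction is insensitive to it.
* **fODF sampling**: amplitudes are reconstructed at 8000 approximately
  equidistant points (a Fibonacci spiral — no icosahedral subdivision has
  exactly 8000 vertices). Peaks are grid local maxima above 0.5 of the
  voxel maximum, antipodally deduplicated with a 25-degree minimum
  separation (at most 3), then refined off-grid by a zooming spherical-cap
  search (final quantization ~0.1 degree).

## Bootstrap orientation PDFs

Model-based residual bootstrap per voxel: the normalized DW signal is fit
with the plain lmax-8 SH basis; the per-direction residuals — rescaled by the
leverage correction `1/sqrt(1 - h_ii)` to undo the fit's shrinkage of the
noise (45 parameters on 61 measurements leaves `h_ii ~ 0.7`) — are resampled
with replacement, added back to the prediction, and CSD is refit; the peak
axes of each replicate form the voxel's orientation PDF as a sample set.
Replicates with no detectable peak mark an isotropic draw. The default of 50
replicates per voxel is a compute/fidelity compromise (dispersion estimates
stabilize well below that; the per-voxel `bootstrap_pdf` API supports any
count). Noise-free data gives near-zero residuals and sub-0.2-degree peak
scatter; at SNR 10 vs 40 the angular dispersion is ~3.8 vs ~0.8 degrees.

## Streamline propagation

PICo-style Monte Carlo: from each seed-region voxel center, a configurable
number of bidirectional streamlines (production default 1000, scaled to 250
in tests and the acceptance script for CPU budget) start along the two
antipodal senses of one drawn orientation. Each step draws one bootstrap
replicate of the current voxel (nearest-voxel lookup, no interpolation); the
replicate's peak most aligned with the incoming direction is taken,
sign-aligned (ties to the first index; isotropic draws fall back to a
uniformly random axis). A step is rejected — terminating that end — when the
turning angle exceeds the curvature threshold (after sign alignment turning
never exceeds 90 degrees, so thresholds of 90 and 180 both reject nothing),
when FA at the entered voxel is below the FA threshold (outside the
gray-matter mask when the exemption is on, everywhere when off), when the
path leaves the volume or the tracking mask, or at `max_steps`. Step size
defaults to half the voxel size.

Determinism and monotonicity: all random draws are pre-generated per
(streamline, sense, step index), so a fixed seed reproduces runs exactly and
tightening a constraint can only truncate a streamline, never redirect it —
the monotone-arrival property under curvature tightening holds structurally,
not just statistically. `Streamline.termination_reason` reports the forward
end's reason; both ends' reasons are stored.

## Connection matrices and validation

SCI (strength): percent of initiated streamlines from A whose path enters any
voxel of B ("reached" = any point rounds into a B voxel; the seed region
does not count as its own target); symmetrized by the maximum of the two
directed measurements. LCI (length): per direction, the mean over seed
voxels (with >= 1 connecting streamline) of the mean arc distance from the
seed to the first entry into the target (the closest entry along either
sense); the symmetric LCI takes the larger directed value. R/R^2 corrections
multiply SCI entries by LCI (or LCI squared) without rescaling.

Validation counts unordered determinate pairs only; predicted-present means
strictly above the threshold. Accuracy = 100 (TP+TN)/(TP+TN+FP+FN); TP rate
TP/(TP+FN); FP rate FP/(FP+TN); %TP = 100 TP/(TP+FP); %TN = 100 TN/(TN+FN)
(NaN where undefined). The threshold scan uses 0..100 in 1% steps (ties at
the optimum break toward the smaller threshold); corrected matrices live on
their own scale, so their scan thresholds are 0..100% *of the matrix
maximum*. Length-binned rates sort determinate pairs by LCI ascending into
five contiguous equal-count bins (remainder `r` gives one extra pair to the
first `r` bins).

The desk-scale phantoms are too clean for the optimum-threshold scan itself
to leave false negatives, so the distance-effect comparison evaluates binned
rates at a fixed representative threshold of 2% (the reported optimum band
is 2–5%), and at the equivalent fraction of the maximum for corrected
matrices.

## Atlas fixtures

The packaged CSVs encode only what the printed record pins down: 40 apparent
false-negative pairs (20 confident) and 18 apparent false-positive pairs
(8 confident), each with its status in the newer quantitative tracer study
(strong/weak/absent/untested: 10 of the FNs were re-tested — 8 confirmed
present, 2 absent; 9 of the FPs — 8 present, 1 absent), the 22-region
vocabulary, and the cross-scheme name map (one region maps to nothing, two
map to the same target, two map to combined name sets). The name `MSTi` is
stored as printed and aliased to `MSTl` without resolving the discrepancy.
The full ternary matrix exists only as a figure raster; users supply any
further truth as CSV.

## Known limitations

* Headline accuracies from the original fixed-brain scans are not
  reproducible here (no deposited data); the phantoms test machinery, not
  tissue realism.
* Single-shell, single-tissue CSD only; no multi-shell/multi-tissue variants.
* The bootstrap PDF is a sample set; very small replicate counts quantize it.
* Thin-tube phantoms sit near the voxelization limit (a radius below ~0.7
  voxels can disconnect the rasterized corridor); the mixed-length phantom's
  long bundle deliberately sits just above it.
* Curvature thresholds >= 90 degrees are inert by construction (sign-aligned
  axial orientations), mirroring the near-null effect reported for
  probabilistic tracking.
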