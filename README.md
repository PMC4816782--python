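# tractvalid

Validation machinery for probabilistic diffusion-MRI tractography against
tracer-derived ground truth, exercised end-to-end on synthetic phantoms with
known inter-region connections.

## The problem

Streamline tractography infers anatomical connections from diffusion MRI, but
its output is hard to trust without a gold standard. In the macaque visual
system, decades of invasive tracer studies provide such a standard: a
region-by-region wiring map in which each pair of cortical areas is known to
be connected, unconnected, or undetermined. A validation experiment runs
probabilistic tractography between the parcellated regions, thresholds the
resulting connection-strength matrix, and asks how many known connections and
non-connections are classified correctly — and how that accuracy responds to
distance corrections and to curvature/FA termination constraints.

This package implements every stage of that experiment:

* **phantom** — synthetic HARDI volumes (Gaussian multi-tensor signal, Rician
  noise) with labelled regions, curved fiber bundles realizing a known
  ternary connection matrix, and the two single-shell acquisition protocols
  (61 directions at b = 4000 s/mm²; 120 at b = 8000);
* **preprocess** — slice-wise 2D Perona–Malik anisotropic smoothing;
* **fodf** — diffusion-tensor fitting (FA) and constrained spherical
  deconvolution (CSD, 45 real even spherical harmonics, lmax 8, fODFs
  reconstructed at 8000 sphere points);
* **tracking** — model-based residual-bootstrap orientation PDFs and
  PICo-style Monte Carlo streamline propagation with curvature and FA
  termination constraints (gray-matter exemption supported);
* **connectome** — symmetric strength (SCI, % of initiated streamlines) and
  length (LCI, mm) matrices, max-symmetrization, R and R² distance
  corrections;
* **validation** — confusion counts over determinate pairs,
  `accuracy = 100·(TP+TN)/(TP+TN+FP+FN)`, TP/FP rates, %TP/%TN, 0–100%
  threshold scans with ROC, and length-binned rates;
* **atlas** — packaged fixtures of the printed tracer-atlas fragments
  (apparent false-negative/false-positive connection tables with their status
  in the newer quantitative tracer study, the 22-region vocabulary, and the
  cross-scheme region-name map).

The original postmortem scans are not publicly deposited, so the headline
accuracies reported for them (~77% and ~70%) are context, not a reproduction
target; the phantoms validate the machinery itself.

## Worked example

```bash
tractvalid run --seed 0 --out results/baseline
# or: python analysis/03_baseline_connectome.py 0
```

runs phantom → CSD → bootstrap PDFs → tracking (250 streamlines/voxel) →
SCI/LCI → threshold scan on the six-region, five-bundle phantom at SNR 20,
and prints:

```
SCI matrix (percent of initiated streamlines):
       R1     R2     R3     R4     R5     R6
R1   0.00  35.82  14.56   0.00   0.00   0.00
R2  35.82   0.00  16.44   0.00   0.00   0.00
R3  14.56  16.44   0.00   0.00   0.00   0.00
R4   0.00   0.00   0.00   0.00  44.22   0.98
R5   0.00   0.00   0.00  44.22   0.00  46.53
R6   0.00   0.00   0.00   0.98  46.53   0.00

optimum acceptance threshold: 1%
accuracy at optimum: 100.0%
confusion at optimum: {'tp': 5, 'tn': 10, 'fp': 0, 'fn': 0}
```

Reading it: the five planted bundles (R1–R2, R1–R3, R2–R3, R4–R5, R5–R6)
score 14.6–46.5% of initiated streamlines, while the strongest spurious pair
(R4–R6, a pass-through across the hub region R5) stays below 1%, so a 1%
acceptance threshold classifies all 15 determinate pairs correctly. The
numbered scripts under `analysis/` continue the study: fODF quality metrics
(`02`), the full threshold scan and ROC (`04`), curvature {70, 80, 90, 180}°
and FA {0, 0.1, 0.2, 0.3} constraint sweeps (`05`), and the distance effect
on a mixed-length phantom (`06`), where the uncorrected longest-length bin
recovers only half of its true connections (TP rate 0.5) and both the R and
R² corrections lift it to 1.0 — at the price of a corrected false positive,
mirroring the known behavior of these corrections.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch at the given seed on the six-region
and mixed-length phantoms (simulation, CSD, bootstrap tracking, matrices,
corrections, threshold scans), prints each run's optimum threshold and
accuracy, and writes the results file; intermediate outputs land under
`results/acceptance_run/`.
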