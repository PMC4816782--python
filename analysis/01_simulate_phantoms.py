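"""Simulate the study phantoms and write their volumes and ground truth.

Three synthetic worlds are produced under results/phantoms/:
* six_region  — five recoverable bundles (one curved) over six regions; the
  main validation phantom (SNR 20, D1-like 61-direction b=4000 scheme);
* mixed_length — bundle lengths from ~5 to ~40 mm, with the longest made thin
  and weak to expose the distance bias of probabilistic tracking;
* arc_bundle  — a tight half-circle used for curvature-constraint experiments.
"""

import sys
from pathlib import Path

import numpy as np

from tractvalid import fileio
from tractvalid import phantom as ph

OUT = Path("results/phantoms")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    scheme = ph.make_scheme(61, 4000.0, 7, rng_seed=SEED)
    for name, maker in (("six_region", ph.six_region_phantom),
                        ("mixed_length", ph.mixed_length_phantom),
                        ("arc_bundle", ph.arc_bundle_phantom)):
        spec = maker(snr=20.0, rng_seed=SEED)
        data = ph.build_phantom(spec, scheme)
        out = OUT / name
        fileio.write_dwi(out, data.dwi)
        fileio.write_nifti(out / "parcellation.nii.gz", data.parcellation, spec.voxel_size)
        fileio.write_nifti(out / "gm_mask.nii.gz", data.gm_mask, spec.voxel_size)
        fileio.write_nifti(out / "tissue_mask.nii.gz", data.tissue_mask, spec.voxel_size)
        data.truth.to_csv(out / "truth.csv")
        n_present = int(np.sum(np.triu(data.truth.states, 1) == 1))
        print(f"{name}: grid {spec.grid_shape}, "
              f"{len(spec.regions)} regions, {len(spec.bundles)} bundles "
              f"({n_present} present pairs), "
              f"{int(data.tissue_mask.sum())} tissue voxels -> {out}")


if __name__ == "__main__":
    main()
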