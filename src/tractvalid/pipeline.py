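"""End-to-end phantom-to-validation pipeline driver.

Executes the full chain — phantom simulation, optional anisotropic smoothing,
tensor/FA fitting, CSD, residual-bootstrap orientation PDFs, Monte Carlo
tracking over a grid of constraint settings, SCI/LCI matrices, distance
corrections, and threshold-scan validation against the phantom's ternary
ground truth — and writes matrices (CSV), volumes (NIfTI-1), streamlines
(TRK), and a deterministic JSON summary.

All randomness derives from one integer seed: the phantom noise, the gradient
scheme rotation, the bootstrap resampling, and the per-region tracking
streams each get an independent child seed, so a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import connectome as cn
from . import fileio, fodf
from . import phantom as ph
from . import preprocess
from . import tracking as tr
from . import validation as va

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "phantom": {"kind": "six_region", "snr": 20.0},
    "scheme": {"name": "D1"},          # D1: 61 dirs at b=4000, 7 b=0
    "preprocess": {"enabled": False, "n_iter": 5},
    "fodf": {"response_fa": 0.8, "n_boot": 50},
    "tracking": {
        "streamlines_per_voxel": 1000,
        "curvature_thresholds": [180.0],
        "fa_thresholds": [0.0],
        "gm_mask_exempt": True,
        "max_steps": 300,
    },
    "corrections": ["none", "R", "R2"],
    "binned_rates_threshold_percent": 2.0,
    "write_streamlines": False,
}

_SCHEMES = {"D1": (61, 4000.0, 7), "D2": (120, 8000.0, 17)}
_PHANTOMS = {
    "six_region": ph.six_region_phantom,
    "mixed_length": ph.mixed_length_phantom,
    "straight_bundle": ph.straight_bundle_phantom,
    "arc_bundle": ph.arc_bundle_phantom,
}


def load_config(path_or_dict) -> dict:
    """Merge a YAML file or dict over the defaults (one level deep)."""
    user = path_or_dict
    if not isinstance(user, dict):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            unknown = set(value) - set(cfg[key])
            if unknown:
                raise ValueError(f"unknown config keys {sorted(unknown)} under {key!r}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _make_scheme(cfg: dict, seed: int) -> ph.GradientScheme:
    name = cfg.get("name", "custom")
    if name in _SCHEMES:
        n_dir, bval, n_b0 = _SCHEMES[name]
    else:
        n_dir, bval, n_b0 = cfg["n_directions"], cfg["bvalue"], cfg["n_b0"]
    return ph.make_scheme(n_dir, bval, n_b0, rng_seed=seed)


def run_pipeline(config, out_dir, seed: int = 0) -> dict:
    """Run the configured pipeline; returns (and writes) the JSON summary."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    root = np.random.SeedSequence(seed)
    seed_phantom, seed_scheme, seed_boot, seed_track = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )
    log.append(f"seeds: phantom={seed_phantom} scheme={seed_scheme} "
               f"bootstrap={seed_boot} tracking={seed_track}")

    stage = "phantom"
    try:
        scheme = _make_scheme(cfg["scheme"], seed_scheme)
        maker = _PHANTOMS[cfg["phantom"]["kind"]]
        kwargs = {k: v for k, v in cfg["phantom"].items() if k != "kind"}
        spec = maker(rng_seed=seed_phantom, **kwargs)
        data = ph.build_phantom(spec, scheme)
        fileio.write_dwi(out, data.dwi)
        fileio.write_nifti(out / "parcellation.nii.gz", data.parcellation, spec.voxel_size)
        fileio.write_nifti(out / "gm_mask.nii.gz", data.gm_mask, spec.voxel_size)
        data.truth.to_csv(out / "truth.csv")
        log.append(f"phantom: {cfg['phantom']['kind']} grid={spec.grid_shape} "
                   f"snr={spec.snr} tissue_voxels={int(data.tissue_mask.sum())}")

        stage = "preprocess"
        dwi = data.dwi
        if cfg["preprocess"]["enabled"]:
            smoothed = preprocess.anisotropic_smooth(
                dwi.signal, n_iter=int(cfg["preprocess"]["n_iter"]))
            dwi = ph.DwiVolume(np.clip(smoothed, 0.0, None), dwi.voxel_size, scheme)
            log.append(f"preprocess: {cfg['preprocess']['n_iter']} iterations")

        stage = "tensor"
        fa_map = tr.fa_volume(dwi, data.tissue_mask)
        fileio.write_nifti(out / "fa.nii.gz", fa_map, spec.voxel_size)

        stage = "csd"
        bval = float(scheme.bvalues.max())
        response = fodf.single_fiber_response(bval, fa=cfg["fodf"]["response_fa"])
        dec = fodf.CsdDeconvolver(scheme, response)
        flat = np.flatnonzero(data.tissue_mask)
        coeffs, _ = dec.fit_batch(
            dwi.signal.reshape(-1, dwi.signal.shape[-1])[flat])
        sh_vol = np.zeros(data.tissue_mask.shape + (coeffs.shape[1],), dtype=np.float32)
        sh_vol.reshape(-1, coeffs.shape[1])[flat] = coeffs
        fileio.write_nifti(out / "fodf_sh.nii.gz", sh_vol, spec.voxel_size)

        stage = "bootstrap"
        pdf = tr.bootstrap_pdf_field(
            dwi, data.tissue_mask, response,
            n_boot=int(cfg["fodf"]["n_boot"]), rng_seed=seed_boot)
        log.append(f"bootstrap: n_boot={cfg['fodf']['n_boot']} "
                   f"isotropic_fraction={pdf.isotropic_fraction:.4f}")

        stage = "tracking"
        tcfg0 = cfg["tracking"]
        results = []
        for curv in tcfg0["curvature_thresholds"]:
            for fa_thr in tcfg0["fa_thresholds"]:
                tcfg = tr.TrackingConfig(
                    streamlines_per_voxel=int(tcfg0["streamlines_per_voxel"]),
                    curvature_threshold=float(curv),
                    fa_threshold=float(fa_thr),
                    gm_mask_exempt=bool(tcfg0["gm_mask_exempt"]),
                    max_steps=int(tcfg0["max_steps"]),
                    rng_seed=seed_track,
                )
                by_region = {
                    lab: tr.track_region(lab, data.parcellation, pdf, fa_map,
                                         data.gm_mask, tcfg,
                                         tracking_mask=data.tissue_mask)
                    for lab in sorted(spec.regions)
                }
                step = tcfg.resolve_step(spec.voxel_size)
                names = {l: spec.name_of(l) for l in spec.regions}
                sci, lci = cn.build_matrices(by_region, data.parcellation,
                                             spec.voxel_size, step, names)
                tag = f"curv{curv:g}_fa{fa_thr:g}"
                sci.to_csv(out / f"sci_{tag}.csv")
                lci.to_csv(out / f"lci_{tag}.csv")
                if cfg["write_streamlines"]:
                    all_sl = [s for sls in by_region.values() for s in sls]
                    fileio.write_trk(out / f"streamlines_{tag}.trk", all_sl,
                                     spec.grid_shape, spec.voxel_size)
                results.append(_validate_block(cfg, data.truth, sci, lci, curv, fa_thr))
                log.append(f"tracking {tag}: "
                           f"{sum(len(v) for v in by_region.values())} streamlines")

        summary = {
            "config": cfg,
            "seed": seed,
            "child_seeds": {"phantom": seed_phantom, "scheme": seed_scheme,
                            "bootstrap": seed_boot, "tracking": seed_track},
            "results": results,
        }
        stage = "summary"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        (out / "pipeline.log").write_text("\n".join(log) + "\n")
        return summary
    except Exception as exc:
        (out / "pipeline.log").write_text(
            "\n".join(log + [f"FAILED at stage {stage}: {exc}"]) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _validate_block(cfg, truth, sci, lci, curv, fa_thr) -> dict:
    """Threshold scans and binned rates for one tracking configuration."""
    block = {"curvature_threshold": float(curv), "fa_threshold": float(fa_thr),
             "corrections": {}}
    ref_pct = float(cfg["binned_rates_threshold_percent"])
    for mode in cfg["corrections"]:
        if mode == "none":
            matrix = sci
            thresholds = None               # 0, 1, ..., 100 percent
            ref_threshold = ref_pct
        else:
            matrix = cn.distance_correct(sci, lci, mode)
            top = float(matrix.values.max())
            thresholds = np.linspace(0.0, top, 101)
            ref_threshold = ref_pct / 100.0 * top
        scan = va.threshold_scan(matrix, truth, thresholds)
        opt_conf = va.confusion(matrix, truth, scan.optimum_threshold)
        binned = None
        if len(truth.pair_indices()) >= 5:
            binned = va.length_binned_rates(matrix, lci, truth, ref_threshold)
        block["corrections"][mode] = {
            "optimum_threshold": scan.optimum_threshold,
            "optimum_accuracy": scan.optimum_accuracy,
            "optimum_confusion": {"tp": opt_conf.tp, "tn": opt_conf.tn,
                                  "fp": opt_conf.fp, "fn": opt_conf.fn},
            "roc": [[float(a), float(b)] for a, b in scan.roc().tolist()],
            "accuracy_by_threshold": scan.table["accuracy"].tolist(),
            "binned_rates": None if binned is None else {
                "threshold": float(ref_threshold),
                "tp_rate": binned["tp_rate"].tolist(),
                "fp_rate": binned["fp_rate"].tolist(),
            },
        }
    return block
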