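"""Bootstrap PDF and streamline propagation tests."""

import numpy as np
import pytest

from tractvalid import fodf, tracking as tr

from conftest import add_rician, angle_deg, single_fiber_signal


def _dispersion_deg(peaks, counts, truth):
    errs = [angle_deg(peaks[b, 0], truth) for b in range(len(counts)) if counts[b] > 0]
    return np.mean(errs)


class TestBootstrapPdf:
    def test_noise_free_peaks_within_1deg(self, scheme_d1, response_d1):
        rng = np.random.default_rng(0)
        sig, v = single_fiber_signal(scheme_d1, rng.normal(size=3))
        peaks, counts = tr.bootstrap_pdf(sig, scheme_d1, response_d1,
                                         n_boot=20, rng_seed=1)
        assert np.all(counts == 1)
        for b in range(20):
            assert angle_deg(peaks[b, 0], v) < 1.0

    def test_dispersion_grows_as_snr_drops(self, scheme_d1, response_d1):
        rng = np.random.default_rng(2)
        sig, v = single_fiber_signal(scheme_d1, rng.normal(size=3))
        disp = {}
        for snr, seed in ((10.0, 3), (40.0, 4)):
            noisy = add_rician(sig, snr=snr, rng=np.random.default_rng(seed))
            peaks, counts = tr.bootstrap_pdf(noisy, scheme_d1, response_d1,
                                             n_boot=500, rng_seed=5)
            disp[snr] = _dispersion_deg(peaks, counts, v)
        assert disp[10.0] > disp[40.0]

    def test_single_replicate(self, scheme_d1, response_d1):
        rng = np.random.default_rng(6)
        sig, _ = single_fiber_signal(scheme_d1, rng.normal(size=3))
        peaks, counts = tr.bootstrap_pdf(sig, scheme_d1, response_d1,
                                         n_boot=1, rng_seed=0)
        assert peaks.shape[0] == 1 and counts.shape == (1,)

    def test_zero_replicates_rejected(self, scheme_d1, response_d1):
        with pytest.raises(ValueError, match="n_boot"):
            tr.bootstrap_pdf(np.ones(len(scheme_d1)), scheme_d1, response_d1,
                             n_boot=0)

    def test_degenerate_voxel_flagged_isotropic(self, scheme_d1, response_d1):
        peaks, counts = tr.bootstrap_pdf(np.zeros(len(scheme_d1)), scheme_d1,
                                         response_d1, n_boot=5, rng_seed=0)
        assert np.all(counts == 0)
        assert np.all(np.isnan(peaks))


class TestPropagate:
    def test_curvature_180_never_terminates_for_curvature(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=50, curvature_threshold=180.0,
                                rng_seed=1)
        sls = straight_run.track(cfg, labels=[1])[1]
        assert all("curvature" not in s.termination_reasons for s in sls)

    def test_fa_zero_never_terminates_for_fa(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=50, fa_threshold=0.0, rng_seed=1)
        sls = straight_run.track(cfg, labels=[1])[1]
        assert all("fa" not in s.termination_reasons for s in sls)

    def test_straight_noise_free_bundle_connects(self, straight_run):
        """On a noise-free straight bundle, nearly all streamlines seeded in
        region 1 pass through region 2."""
        cfg = tr.TrackingConfig(streamlines_per_voxel=1000, rng_seed=2)
        sls = straight_run.track(cfg, labels=[1])[1]
        parc = straight_run.data.parcellation
        vs = straight_run.spec.voxel_size
        shape = np.array(parc.shape)
        reached = 0
        for s in sls:
            vox = np.rint(s.points / vs).astype(int)
            ok = np.all((vox >= 0) & (vox < shape), axis=1)
            if np.any(parc[tuple(vox[ok].T)] == 2):
                reached += 1
        assert reached / len(sls) >= 0.95

    def test_seed_outside_volume_rejected(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=1)
        with pytest.raises(ValueError, match="outside"):
            tr.propagate(np.array([-50.0, 0.0, 0.0]), straight_run.pdf,
                         straight_run.fa, straight_run.data.gm_mask, cfg)

    def test_step_distances_equal_step_size(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=1, step_size=0.5, rng_seed=3)
        sl = tr.propagate(np.array([7.0, 4.0, 4.0]), straight_run.pdf,
                          straight_run.fa, straight_run.data.gm_mask, cfg,
                          tracking_mask=straight_run.data.tissue_mask)
        d = np.linalg.norm(np.diff(sl.points, axis=0), axis=1)
        assert np.allclose(d, 0.5, atol=1e-6)
        assert sl.length == pytest.approx(d.sum())

    def test_termination_reason_vocabulary(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=20, rng_seed=4, max_steps=5)
        sls = straight_run.track(cfg, labels=[1])[1]
        allowed = {"curvature", "fa", "mask-exit", "max-steps", "left-volume"}
        assert {r for s in sls for r in s.termination_reasons} <= allowed


class TestTrackRegion:
    def test_streamline_count(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=1000, rng_seed=5)
        sls = straight_run.track(cfg, labels=[1])[1]
        n_vox = int(np.sum(straight_run.data.parcellation == 1))
        assert len(sls) == 1000 * n_vox

    def test_single_streamline(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=1, rng_seed=5)
        assert len(straight_run.track(cfg, labels=[1])[1]) == \
            int(np.sum(straight_run.data.parcellation == 1))

    def test_deterministic_for_fixed_seed(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=30, rng_seed=6)
        a = straight_run.track(cfg, labels=[1])[1]
        b = straight_run.track(cfg, labels=[1])[1]
        assert len(a) == len(b)
        for s, t in zip(a, b):
            assert np.array_equal(s.points, t.points)
            assert s.termination_reasons == t.termination_reasons

    def test_empty_region_rejected(self, straight_run):
        cfg = tr.TrackingConfig(streamlines_per_voxel=1)
        with pytest.raises(ValueError, match="empty"):
            tr.track_region(99, straight_run.data.parcellation, straight_run.pdf,
                            straight_run.fa, straight_run.data.gm_mask, cfg)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"streamlines_per_voxel": 0},
        {"fa_threshold": 1.0},
        {"fa_threshold": -0.1},
        {"curvature_threshold": 0.0},
        {"curvature_threshold": 200.0},
        {"step_size": -1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tr.TrackingConfig(**kwargs)

    def test_step_cannot_exceed_voxel(self):
        cfg = tr.TrackingConfig(step_size=2.0)
        with pytest.raises(ValueError, match="voxel"):
            cfg.resolve_step(1.0)
        assert tr.TrackingConfig().resolve_step(1.0) == 0.5
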