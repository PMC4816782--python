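"""Tensor fit, single-fiber response, CSD, and fODF sampling tests."""

import numpy as np
import pytest

from tractvalid import fodf, phantom as ph, spherical as sp

from conftest import add_rician, angle_deg, single_fiber_signal


class TestTensorFit:
    def test_isotropic_signal_gives_zero_fa(self, scheme_d1):
        sig = np.exp(-scheme_d1.bvalues * 0.5e-3)
        tf = fodf.fit_tensor(sig, scheme_d1)
        assert tf.fa < 1e-6

    def test_degenerate_tensor_gives_fa_one(self):
        assert fodf.fa_from_eigenvalues(np.array([1.5e-3, 0.0, 0.0])) == pytest.approx(1.0)

    def test_recovers_closed_form_fa_and_direction(self, scheme_d1):
        # closed-form FA of eigenvalues (1.7, 0.3, 0.3)e-3
        ev = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        expected_fa = np.sqrt(1.5 * np.sum((ev - ev.mean()) ** 2) / np.sum(ev**2))
        rng = np.random.default_rng(4)
        v = rng.normal(size=3)
        sig, v = single_fiber_signal(scheme_d1, v, lpar=ev[0], lperp=ev[1])
        tf = fodf.fit_tensor(sig, scheme_d1)
        assert tf.fa == pytest.approx(expected_fa, abs=1e-3)
        assert angle_deg(tf.principal_direction, v) < 1.0
        assert np.all(np.diff(tf.eigenvalues) <= 0)

    def test_nonpositive_signals_clamped_with_warning(self, scheme_d1):
        sig = np.ones(len(scheme_d1))
        sig[10] = 0.0
        with pytest.warns(UserWarning, match="clamped"):
            fodf.fit_tensor(sig, scheme_d1)


class TestResponse:
    def test_l0_equals_spherical_mean_by_quadrature(self):
        resp = fodf.single_fiber_response(4000.0, fa=0.8)
        lpar, lperp = fodf.axially_symmetric_eigenvalues(
            0.8, (ph.LAMBDA_PARALLEL + 2 * ph.LAMBDA_PERP) / 3.0)
        mu, w = np.polynomial.legendre.leggauss(128)
        mean_signal = 0.5 * np.sum(w * np.exp(-4000.0 * (lperp + (lpar - lperp) * mu**2)))
        assert resp.zonal[0] == pytest.approx(np.sqrt(4 * np.pi) * mean_signal, rel=1e-8)

    def test_isotropic_limit_kills_higher_orders(self):
        resp7 = fodf.single_fiber_response(4000.0, fa=1e-7)
        assert np.all(np.abs(resp7.zonal[1:]) < 1e-6 * abs(resp7.zonal[0]))
        # higher-order content scales down with fa
        resp3 = fodf.single_fiber_response(4000.0, fa=1e-3)
        assert np.all(np.abs(resp7.zonal[1:]) < np.abs(resp3.zonal[1:]))

    def test_l2_sharpens_with_bvalue_at_fixed_md(self):
        # the deconvolution kernel gets sharper with b: the l=2 content grows
        # relative to l=0 (absolute coefficients shrink with exp(-b*lambda))
        r4 = fodf.single_fiber_response(4000.0, fa=0.8)
        r8 = fodf.single_fiber_response(8000.0, fa=0.8)
        assert abs(r8.zonal[1] / r8.zonal[0]) > abs(r4.zonal[1] / r4.zonal[0])

    def test_fa_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fodf.single_fiber_response(4000.0, fa=1.0)

    def test_requested_fa_is_realized(self):
        lpar, lperp = fodf.axially_symmetric_eigenvalues(0.8, 0.45e-3)
        assert fodf.fa_from_eigenvalues(np.array([lpar, lperp, lperp])) \
            == pytest.approx(0.8, abs=1e-12)
        assert (lpar + 2 * lperp) / 3 == pytest.approx(0.45e-3)


class TestCsd:
    def test_single_fiber_peak_within_2deg(self, scheme_d1, response_d1,
                                           deconvolver_d1):
        rng = np.random.default_rng(7)
        for _ in range(5):
            sig, v = single_fiber_signal(scheme_d1, rng.normal(size=3))
            peaks, _ = fodf.fodf_peaks(deconvolver_d1.fit(sig))
            assert len(peaks) == 1
            assert angle_deg(peaks[0], v) < 2.0

    def test_90deg_crossing_resolved(self, scheme_d1, deconvolver_d1):
        rng = np.random.default_rng(8)
        v = rng.normal(size=3); v /= np.linalg.norm(v)
        u = np.cross(v, rng.normal(size=3)); u /= np.linalg.norm(u)
        s1, _ = single_fiber_signal(scheme_d1, v)
        s2, _ = single_fiber_signal(scheme_d1, u)
        coeffs = deconvolver_d1.fit(0.5 * (s1 + s2))
        amps = fodf.sample_fodf(coeffs, fodf.fodf_sample_directions())
        peaks, vals = fodf.fodf_peaks(coeffs, relative_threshold=0.5)
        assert len(peaks) == 2
        for p in peaks:
            assert min(angle_deg(p, v), angle_deg(p, u)) < 5.0
        assert np.all(vals > 0.5 * amps.max())

    def test_isotropic_signal_gives_flat_fodf(self, scheme_d1, deconvolver_d1):
        sig = np.exp(-scheme_d1.bvalues * 0.35e-3)
        sig[scheme_d1.b0_mask] = 1.0
        amps = fodf.sample_fodf(deconvolver_d1.fit(sig),
                                fodf.fodf_sample_directions())
        assert amps.std() / amps.mean() < 0.05

    def test_rotational_equivariance(self, scheme_d1, deconvolver_d1):
        rng = np.random.default_rng(9)
        for _ in range(20):
            sig, v = single_fiber_signal(scheme_d1, rng.normal(size=3))
            peaks, _ = fodf.fodf_peaks(deconvolver_d1.fit(sig))
            assert angle_deg(peaks[0], v) < 2.0

    def test_constraint_effective_on_noisy_single_fiber(self, scheme_d1,
                                                        deconvolver_d1):
        rng = np.random.default_rng(10)
        sig, _ = single_fiber_signal(scheme_d1, rng.normal(size=3))
        noisy = add_rician(np.tile(sig, (50, 1)), snr=20.0, rng=rng)
        coeffs, _ = deconvolver_d1.fit_batch(noisy)
        amps = fodf.sample_fodf(coeffs, fodf.fodf_sample_directions())
        assert np.all(amps.min(axis=1) >= -1e-4 * amps.max(axis=1))

    def test_nonconvergence_returns_last_iterate_with_warning(self, scheme_d1,
                                                              response_d1):
        dec = fodf.CsdDeconvolver(scheme_d1, response_d1, max_iter=1)
        rng = np.random.default_rng(11)
        sig, _ = single_fiber_signal(scheme_d1, rng.normal(size=3))
        noisy = add_rician(sig, snr=10.0, rng=rng)
        with pytest.warns(UserWarning, match="did not converge"):
            coeffs = dec.fit(noisy)
        assert np.any(coeffs != 0)

    def test_nonpositive_response_rejected(self, scheme_d1, response_d1):
        bad = fodf.ResponseFunction(-response_d1.zonal, 4000.0)
        with pytest.raises(ValueError, match="l=0"):
            fodf.CsdDeconvolver(scheme_d1, bad)


class TestSampleFodf:
    def test_l0_only_is_constant(self):
        coeffs = np.zeros(45)
        coeffs[0] = 2.0
        amps = fodf.sample_fodf(coeffs, fodf.fodf_sample_directions())
        assert np.allclose(amps, 2.0 / np.sqrt(4 * np.pi))

    def test_antipodal_symmetry(self):
        rng = np.random.default_rng(12)
        coeffs = rng.normal(size=45)
        dirs = rng.normal(size=(30, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert np.allclose(fodf.sample_fodf(coeffs, dirs),
                           fodf.sample_fodf(coeffs, -dirs), atol=1e-10)

    def test_matches_independent_legendre_oracle(self):
        from test_spherical import oracle_real_sh
        rng = np.random.default_rng(13)
        coeffs = rng.normal(size=45)
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert np.allclose(fodf.sample_fodf(coeffs, dirs),
                           oracle_real_sh(dirs, 8) @ coeffs, atol=1e-8)

    def test_sample_count_contract(self):
        assert len(fodf.fodf_sample_directions()) == 8000
        assert fodf.FodfField(np.zeros((0, 45)), np.zeros((2, 2, 2), bool)) \
            .sample_directions.shape == (8000, 3)

    def test_coefficient_count_contract(self):
        assert sp.n_coefficients(8) == 45
        with pytest.raises(ValueError):
            fodf.FodfField(np.zeros((3, 44)), np.ones((3, 1, 1), bool))
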