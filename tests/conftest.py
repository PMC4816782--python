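"""Shared fixtures: gradient schemes, responses, and phantom pipeline products.

The expensive session fixtures (bootstrap PDF fields over whole phantoms) are
computed once and shared between the tracking, connectome, and acceptance
tests.  All randomness is seeded; streamline counts are scaled below the
production default of 1000/voxel to keep the suite inside a CPU budget (the
statistics involved resolve connection strengths well below the 1% threshold
grid at these counts).
"""

from __future__ import annotations

import numpy as np
import pytest

from tractvalid import connectome as cn
from tractvalid import fodf
from tractvalid import phantom as ph
from tractvalid import tracking as tr


@pytest.fixture(scope="session")
def scheme_d1():
    return ph.make_scheme(61, 4000.0, 7, rng_seed=3)


@pytest.fixture(scope="session")
def response_d1():
    return fodf.single_fiber_response(4000.0)


@pytest.fixture(scope="session")
def deconvolver_d1(scheme_d1, response_d1):
    return fodf.CsdDeconvolver(scheme_d1, response_d1)


def single_fiber_signal(scheme, direction, s0=1.0,
                        lpar=ph.LAMBDA_PARALLEL, lperp=ph.LAMBDA_PERP):
    """Noise-free signal of one axially symmetric tensor along ``direction``."""
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    att = np.exp(-scheme.bvalues * (lperp + (lpar - lperp)
                                    * (scheme.directions @ v) ** 2))
    att[scheme.b0_mask] = 1.0
    return s0 * att, v


def add_rician(signal, snr, rng, s0=1.0):
    sigma = s0 / snr
    n = rng.normal(scale=sigma, size=signal.shape + (2,))
    return np.sqrt((signal + n[..., 0]) ** 2 + n[..., 1] ** 2)


def angle_deg(u, v):
    return np.rad2deg(np.arccos(min(1.0, abs(float(np.dot(u, v))))))


class PhantomRun:
    """Phantom products plus tracking helpers shared by several tests."""

    def __init__(self, spec, scheme, n_boot=50, seed_pdf=11):
        self.spec = spec
        self.scheme = scheme
        self.data = ph.build_phantom(spec, scheme)
        self.response = fodf.single_fiber_response(float(scheme.bvalues.max()))
        self.pdf = tr.bootstrap_pdf_field(
            self.data.dwi, self.data.tissue_mask, self.response,
            n_boot=n_boot, rng_seed=seed_pdf)
        self.fa = tr.fa_volume(self.data.dwi, self.data.tissue_mask)

    def track(self, config, labels=None, gm_mask=None):
        labels = sorted(self.spec.regions) if labels is None else labels
        gm = self.data.gm_mask if gm_mask is None else gm_mask
        return {
            lab: tr.track_region(lab, self.data.parcellation, self.pdf, self.fa,
                                 gm, config, tracking_mask=self.data.tissue_mask)
            for lab in labels
        }

    def matrices(self, by_region, config):
        step = config.resolve_step(self.spec.voxel_size)
        names = {l: self.spec.name_of(l) for l in self.spec.regions}
        return cn.build_matrices(by_region, self.data.parcellation,
                                 self.spec.voxel_size, step, names)


@pytest.fixture(scope="session")
def six_region_run(scheme_d1):
    return PhantomRun(ph.six_region_phantom(snr=20.0, rng_seed=0), scheme_d1)


@pytest.fixture(scope="session")
def mixed_length_run(scheme_d1):
    return PhantomRun(ph.mixed_length_phantom(snr=20.0, rng_seed=0), scheme_d1)


@pytest.fixture(scope="session")
def arc_run(scheme_d1):
    return PhantomRun(ph.arc_bundle_phantom(radius_mm=1.3, snr=20.0, rng_seed=0),
                      scheme_d1)


@pytest.fixture(scope="session")
def straight_run(scheme_d1):
    return PhantomRun(ph.straight_bundle_phantom(length_mm=10.0, snr=np.inf),
                      scheme_d1, n_boot=20)
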