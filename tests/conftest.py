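"""Shared fixtures: gradient scheme, constructed single voxels, small phantoms."""

import numpy as np
import pytest

from tractlife.core import ImageGrid, Volume
from tractlife.local_model import deconvolve_fod, estimate_response, fit_tensor, stick_response
from tractlife.phantom import default_gradient_table, generate_phantom, make_u_bundle_spec


@pytest.fixture(scope="session")
def gtab():
    return default_gradient_table()


@pytest.fixture(scope="session")
def single_voxel_grid():
    return ImageGrid.isotropic((1, 1, 1), 2.0)


@pytest.fixture(scope="session")
def stick_signal(gtab):
    """Noiseless multi-compartment stick signal factory for one voxel."""

    def make(t, f=1.0, s0=100.0, d_axial=1.7e-3, d_radial=0.0, d_iso=3.0e-3):
        t = np.asarray(t, dtype=float)
        t = t / np.linalg.norm(t)
        b, G = gtab.bvals, gtab.bvecs
        att = f * np.exp(-b * (d_radial + (d_axial - d_radial) * (G @ t) ** 2))
        return s0 * (att + (1 - f) * np.exp(-b * d_iso))

    return make


@pytest.fixture(scope="session")
def phantom():
    """Default noisy two-session phantom (seed fixed)."""
    spec = make_u_bundle_spec(seed=7)
    sessions, truth = generate_phantom(spec)
    return spec, sessions, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = make_u_bundle_spec(seed=3, noise_sigma=0.0)
    sessions, truth = generate_phantom(spec)
    return spec, sessions, truth


@pytest.fixture(scope="session")
def phantom_fod(phantom):
    """FOD volume fitted on session 1 of the default phantom."""
    spec, sessions, truth = phantom
    wm = truth.wm_mask.data.astype(bool)
    tensor = fit_tensor(sessions[0], spec.gtab, wm)
    response = estimate_response(sessions[0], spec.gtab, tensor)
    fod = deconvolve_fod(sessions[0], spec.gtab, response, mask=wm)
    return fod


@pytest.fixture(scope="session")
def analytic_response(gtab):
    return stick_response(gtab, d_axial=1.7e-3, d_radial=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
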