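"""Shared fixtures: phantoms and reconstructions reused across test modules.

Everything is generated programmatically and seeded; the expensive default
noiseless reconstruction is session-scoped so fidelity, curve and label
tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import ktperf as kp


@pytest.fixture(scope="session")
def control_phantom():
    """Default control phantom (128x128, 60 frames, noiseless)."""
    return kp.render_phantom(kp.PhantomConfig())


@pytest.fixture(scope="session")
def infarct_phantom():
    """Infarct phantom: anterolateral MBF 1.2, remote sectors 7.3."""
    return kp.render_phantom(kp.PhantomConfig.infarct())


@pytest.fixture(scope="session")
def small_phantom():
    """32x32, 20-frame phantom for fast reconstruction tests."""
    return kp.render_phantom(kp.PhantomConfig(grid_size=32, n_frames=20))


@pytest.fixture(scope="session")
def control_recon_noiseless(control_phantom):
    """Noiseless default phantom encoded at R=10 with 3 training profiles,
    reconstructed with defaults, plus the fully sampled reference."""
    series, gt = control_phantom
    n_ky = series.data.shape[1]
    pattern = kp.make_pattern(n_ky, series.n_frames, R=10, n_train=3)
    kt = kp.encode(series, pattern, noise_sd=0.0)
    training = kp.extract_training(kt, pattern)
    basis = kp.build_basis(training, 8)
    recon = kp.unfold(kt, pattern, basis)
    full = kp.encode(series, kp.make_pattern(n_ky, series.n_frames, R=1, n_train=0))
    reference = kp.recon_reference(full)
    return {"series": series, "gt": gt, "pattern": pattern, "recon": recon, "reference": reference}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
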