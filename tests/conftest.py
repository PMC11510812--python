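"""Shared fixtures: a tiny simulation bundle for fast unit tests and the
scaled-down study bundle (session-scoped) for the end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from spectral_n2i import recon
from spectral_n2i.pipeline import make_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    """16 channels, 32x32 phantom, 120 angles: fast but fully featured."""
    return make_fixture((16, 32, 32), seed=7, n_angles=120)


@pytest.fixture(scope="session")
def study_bundle():
    """The scaled-down study: 32 channels, 64x64 phantom, 360 angles, K=4."""
    bundle = make_fixture((32, 64, 64), seed=1)
    sino = bundle["noisy_sinogram"]
    full = recon.fbp_channelwise(sino)
    _, subs = recon.split_angles(sino, 4)
    bundle["fbp_full"] = full
    bundle["fbp_subsets"] = [recon.fbp_channelwise(s) for s in subs]
    return bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
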