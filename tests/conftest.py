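"""Shared fixtures: tiny cohorts and small networks sized for fast tests."""

import numpy as np
import pytest

from vista.model import BackboneConfig, SimTAConfig, ViSTANetwork
from vista.preprocess import FollowUpSeries, series_from_synthetic
from vista.synth import simulate_cohort

TINY_BACKBONE = dict(channels=(4, 8, 8, 8), dim=8)
TINY_PATCH = 16


@pytest.fixture(scope="session")
def tiny_cohort():
    """60 preprocessed synthetic series at 16 mm patches (session-cached)."""
    cohort = simulate_cohort(60, seed=7)
    return [series_from_synthetic(s, patch_size=TINY_PATCH) for s in cohort]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_network(rng=None, dtype=np.float32, patchable=True, **simta_kw):
    """A small ViSTA network compatible with 16^3 (or 8^3) patches."""
    rng = rng if rng is not None else np.random.default_rng(0)
    simta = SimTAConfig(dim=TINY_BACKBONE["dim"], **simta_kw)
    return ViSTANetwork(BackboneConfig(**TINY_BACKBONE), simta, rng, dtype=dtype)


def toy_series(rng, n_steps=3, patch=TINY_PATCH, gap=60.0):
    """A random follow-up series with evenly spaced visits."""
    times = np.arange(n_steps, dtype=float) * gap
    patches = rng.random((n_steps, patch, patch, patch)).astype(np.float32)
    volumes = np.linspace(100, 200, n_steps)
    return FollowUpSeries(series_id="T0", times=times, patches=patches,
                          volumes=volumes, label="IA")
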