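"""Shared fixtures: small simulated cohorts and rendered scenes."""

import numpy as np
import pytest

import shadowtrack as st
from shadowtrack.simulate import AgentParams, RenderParams, simulate_cohort, render_frames


@pytest.fixture(scope="session")
def small_truth():
    """8 agents, 20 s, quarter-size canvas, no stimulus."""
    params = AgentParams(n_agents=8, landing_rate=0.2)
    schedule = st.build_protocol("none", recording_duration=20.0)
    return simulate_cohort(params, schedule, 20.0, seed=11, canvas=(320, 240))


@pytest.fixture(scope="session")
def small_render(small_truth):
    rp = RenderParams(width=320, height=240)
    return render_frames(small_truth, rp, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def render_single_blob(x, y, sx=2.5, sy=2.0, theta=0.7, contrast=115.0,
                       noise_sd=2.0, shape=(120, 160), background=200.0,
                       seed=0):
    """Render one blob with known appearance; returns (frame, background)."""
    h, w = shape
    img = np.full((h, w), background)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - x, yy - y
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    img -= contrast * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    frame = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return frame, np.full((h, w), background)
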