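import numpy as np
import pytest

from ethotrack.arena import (
    RenderConfig,
    render_frames,
    simulate_trial,
)


@pytest.fixture(scope="session")
def short_trial():
    """A 15-s robot-exposed trial used across tracking and metric tests."""
    return simulate_trial(duration=15.0, treatment="robot_exposed", seed=3)


@pytest.fixture(scope="session")
def render_config():
    return RenderConfig()


@pytest.fixture(scope="session")
def rendered_clip(short_trial, render_config):
    """Noise-on, miss-free rendering of the short trial."""
    return render_frames(short_trial, render_config, seed=1)


@pytest.fixture(scope="session")
def tracked_clip(rendered_clip, short_trial, render_config):
    from ethotrack.tracking import track_trial

    return track_trial(
        rendered_clip.frames, render_config, short_trial.geometry, fps=short_trial.fps
    )
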