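import numpy as np
import pytest

from anttrail import (
    ArenaConfig,
    RenderParams,
    WalkParams,
    render_frames,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def small_arena() -> ArenaConfig:
    """Reduced-resolution arena (180 x 320 px) used throughout the suite."""
    return ArenaConfig(width_mm=160.0, height_mm=90.0, px_per_mm=2.0,
                       frame_rate_hz=25.0, duration_s=8.0)


@pytest.fixture(scope="session")
def trail(small_arena):
    return small_arena.default_trail()


@pytest.fixture(scope="session")
def walk_traj(small_arena, trail):
    return simulate_trajectory(
        WalkParams(trail_attraction=1.0, seed=11), small_arena, trail
    )


@pytest.fixture(scope="session")
def clean_video(walk_traj, small_arena, trail):
    """Noise-free rendered video of the session walk."""
    return render_frames(walk_traj, small_arena, RenderParams(), trail)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
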