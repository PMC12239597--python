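import numpy as np
import pytest

from gearbelt import synth
from gearbelt.track import Track


@pytest.fixture
def small_meta():
    """Compact field of view adequate for a 5 µm cell on a ~1 µm tether."""
    return synth.VideoMeta(n_frames=150, shape_px=(128, 128))


@pytest.fixture
def spot_meta():
    return synth.VideoMeta(n_frames=150, shape_px=(48, 144), bit_depth=16)


def make_straight_track(speed_um_s, duration_s=20.0, fps=15.0, heading_rad=0.0,
                        track_id=0, start=(0.0, 0.0)):
    t = np.arange(int(round(duration_s * fps)) + 1) / fps
    return Track(
        track_id=track_id,
        t_s=t,
        x_um=start[0] + speed_um_s * t * np.cos(heading_rad),
        y_um=start[1] + speed_um_s * t * np.sin(heading_rad),
    )


def make_circular_track(radius_um, period_s, n_samples=900, track_id=0):
    t = np.linspace(0.0, period_s, n_samples, endpoint=False)
    phi = 2 * np.pi * t / period_s
    return Track(
        track_id=track_id,
        t_s=t,
        x_um=radius_um * np.cos(phi),
        y_um=radius_um * np.sin(phi),
    )
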