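import numpy as np
import pandas as pd
import pytest

from magbehave.behavior import KEYPOINTS, KeypointTrack, track_columns


def make_track(
    center_xy: np.ndarray,
    frame_rate: float = 2.5,
    heading: np.ndarray | None = None,
    arena_size: tuple[float, float] = (26.5, 26.5),
) -> KeypointTrack:
    """Build a track from a center path; other keypoints ride rigidly.

    ``heading`` (rad) orients the nose 3.5 cm ahead of the center; default
    heading is 0 (nose toward +x).
    """
    n = len(center_xy)
    t = np.arange(n) / frame_rate
    if heading is None:
        heading = np.zeros(n)
    offs = {
        "nose": (3.5, 0.0),
        "center": (0.0, 0.0),
        "forepaws": (1.5, 0.8),
        "hindpaws": (-1.5, -0.8),
        "tail": (-4.0, 0.0),
    }
    cols = {"t": t}
    c, s = np.cos(heading), np.sin(heading)
    for kp in KEYPOINTS:
        dx, dy = offs[kp]
        cols[f"{kp}_x"] = center_xy[:, 0] + c * dx - s * dy
        cols[f"{kp}_y"] = center_xy[:, 1] + s * dx + c * dy
    return KeypointTrack(
        data=pd.DataFrame(cols, columns=track_columns()),
        frame_rate=frame_rate,
        arena_size=arena_size,
    )


@pytest.fixture
def static_track():
    """60 s perfectly static track at the analysis rate."""
    xy = np.tile([10.0, 10.0], (150, 1))
    return make_track(xy)
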