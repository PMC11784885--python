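import numpy as np
import pytest

from drowsekit import KeypointMap, LandmarkFrame
from drowsekit.landmarks import N_MESH_POINTS


@pytest.fixture
def keypoints():
    return KeypointMap()


def build_frame(
    kp: KeypointMap,
    left_eye_x=(100.0, 130.0),
    left_gaps=(6.0, 8.0, 6.0),
    right_eye_x=(200.0, 230.0),
    right_gaps=(6.0, 8.0, 6.0),
    mouth_x=(90.0, 130.0),
    mouth_gaps=(30.0, 36.0, 30.0),
    frame_index=0,
) -> LandmarkFrame:
    """Minimal mesh with the ratio keypoints at controlled positions.

    Vertical pairs are centred on y=0 (eyes) and y=100 (mouth); the gap
    arguments are the |Δy| separations that enter the ratio numerators.
    """
    pts = np.zeros((N_MESH_POINTS, 2))
    pts[kp.left_eye_width[0]] = (left_eye_x[0], 0.0)
    pts[kp.left_eye_width[1]] = (left_eye_x[1], 0.0)
    pts[kp.right_eye_width[0]] = (right_eye_x[0], 0.0)
    pts[kp.right_eye_width[1]] = (right_eye_x[1], 0.0)
    for (top, bot), gap, x in zip(kp.left_eye_vertical, left_gaps,
                                  (105.0, 115.0, 125.0)):
        pts[top] = (x, -gap / 2)
        pts[bot] = (x, gap / 2)
    for (top, bot), gap, x in zip(kp.right_eye_vertical, right_gaps,
                                  (205.0, 215.0, 225.0)):
        pts[top] = (x, -gap / 2)
        pts[bot] = (x, gap / 2)
    pts[kp.mouth_width[0]] = (mouth_x[0], 100.0)
    pts[kp.mouth_width[1]] = (mouth_x[1], 100.0)
    for (top, bot), gap, x in zip(kp.mouth_vertical, mouth_gaps,
                                  (100.0, 110.0, 120.0)):
        pts[top] = (x, 100.0 - gap / 2)
        pts[bot] = (x, 100.0 + gap / 2)
    return LandmarkFrame(frame_index=frame_index, points=pts)


@pytest.fixture
def hand_frame(keypoints):
    """The worked example: eye width 30, gaps 6/8/6; mouth width 40, gaps 30/36/30."""
    return build_frame(keypoints)
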