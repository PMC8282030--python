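import numpy as np
import pandas as pd
import pytest

from spiderpld.config import AnalysisParams, TimelineSpec
from spiderpld.synthetic import make_toy_walk
from spiderpld.tracks import JointTrackSet, rescale_to_box


@pytest.fixture(scope="session")
def toy_tracks() -> JointTrackSet:
    """A 72-frame, 27-point walking track rescaled to the stimulus box."""
    return rescale_to_box(make_toy_walk(seed=1))


@pytest.fixture(scope="session")
def spec() -> TimelineSpec:
    return TimelineSpec()


@pytest.fixture(scope="session")
def analysis() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture
def tiny_track_table() -> pd.DataFrame:
    """2-frame, 2-point long-format table."""
    return pd.DataFrame(
        {
            "frame": [0, 0, 1, 1],
            "label": ["a", "b", "a", "b"],
            "x_px": [0.0, 10.0, 1.0, 11.0],
            "y_px": [0.0, 5.0, 0.0, 5.0],
            "visible": [True, True, True, True],
        }
    )


def track_from_positions(positions, visible=None, labels=None, leg_ids=None) -> JointTrackSet:
    positions = np.asarray(positions, dtype=float)
    n_frames, n_points = positions.shape[:2]
    if visible is None:
        visible = np.ones((n_frames, n_points), dtype=bool)
    if labels is None:
        labels = [f"p{i}" for i in range(n_points)]
    if leg_ids is None:
        leg_ids = [None] * n_points
    return JointTrackSet(labels=labels, leg_ids=leg_ids, positions=positions, visible=visible)
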