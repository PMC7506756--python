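import numpy as np
import pytest

from pupilfatigue.io_frames import PupilTimeSeries


def build_blink_series(
    run_lengths=(6, 1, 5, 8, 6),
    n_frames=300,
    fps=30.0,
    open_area=1200.0,
):
    """A series whose zero frames form exactly the given maximal runs.

    Runs are spread through the recording with non-zero gaps between and
    around them, mirroring the worked blink-counting example of a 10-s
    recording at 30 fps.
    """
    areas = np.full(n_frames, open_area)
    n_gaps = len(run_lengths) + 1
    gap = (n_frames - sum(run_lengths)) // n_gaps
    assert gap >= 1, "runs do not fit with non-zero separators"
    pos = gap
    for run in run_lengths:
        areas[pos : pos + run] = 0.0
        pos += run + gap
    return PupilTimeSeries(areas=areas, fps=fps)


@pytest.fixture
def worked_example_series():
    """10-s, 30-fps series with five zero-runs of lengths 6, 1, 5, 8, 6."""
    return build_blink_series()
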