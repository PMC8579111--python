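import numpy as np
import pytest

from phenolda.arena import TrackingSeries


@pytest.fixture
def straight_series() -> TrackingSeries:
    """10 cm straight line covered in 2 s (5 frames at 2 fps)."""
    t = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
    x = np.array([0.0, 2.5, 5.0, 7.5, 10.0])
    y = np.zeros(5)
    return TrackingSeries("m1", fps=2.0, t=t, body_x=x, body_y=y)


def make_series(
    x: np.ndarray, y: np.ndarray, fps: float = 25.0, subject: str = "m1"
) -> TrackingSeries:
    t = np.arange(len(x)) / fps
    return TrackingSeries(subject, fps, t, np.asarray(x, float), np.asarray(y, float))
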