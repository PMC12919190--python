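import numpy as np
import pytest

from kinescore.pose import PoseSequence
from kinescore.segmentation import TaskWindow


def make_sequence(coords: dict[str, np.ndarray], fps: float = 30.0,
                  confidence: float = 0.9, meta: dict | None = None
                  ) -> PoseSequence:
    """Build a PoseSequence from per-joint (T, 2) coordinate arrays."""
    joints = list(coords)
    n = len(next(iter(coords.values())))
    data = np.empty((n, len(joints), 3))
    for j, name in enumerate(joints):
        xy = np.asarray(coords[name], dtype=float)
        data[:, j, :2] = xy
        data[:, j, 2] = confidence
        missing = ~np.isfinite(xy).all(axis=1)
        data[missing, j, :] = np.nan
    return PoseSequence(joints, data, fps, meta=dict(meta or {}))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def full_window():
    def _make(seq) -> TaskWindow:
        return TaskWindow(0, seq.n_frames)
    return _make
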