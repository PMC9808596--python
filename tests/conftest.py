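import numpy as np
import pytest

from rehabsense.types import EdaSegment, MotionSegment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_segment(
    t,
    xyz,
    sensor="head",
    tag="task",
    study_day=1,
    segment_id="seg1",
    action_class=None,
):
    return MotionSegment(
        segment_id=segment_id,
        sensor=sensor,
        tag=tag,
        study_day=study_day,
        t=np.asarray(t, dtype=float),
        xyz=np.asarray(xyz, dtype=float),
        action_class=action_class,
    )


def random_segment(rng, n=100, dt=1 / 30, **kwargs):
    t = np.arange(n) * dt
    xyz = np.cumsum(rng.normal(scale=0.01, size=(n, 3)), axis=0)
    return make_segment(t, xyz, **kwargs)


def make_eda_segment(values, rate=4.0, segment_id="e1", study_day=1, action_class=None):
    values = np.asarray(values, dtype=float)
    return EdaSegment(
        segment_id=segment_id,
        study_day=study_day,
        t=np.arange(values.size) / rate,
        values=values,
        action_class=action_class,
    )
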