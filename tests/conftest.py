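import numpy as np
import pytest

from baduanjin import synth
from baduanjin.bvh import MotionSequence
from baduanjin.quat import convert_motion


MINIMAL_BVH = """\
HIERARCHY
ROOT Hips
{
  OFFSET 0.0 0.0 0.0
  CHANNELS 6 Xposition Yposition Zposition Zrotation Xrotation Yrotation
  JOINT Spine
  {
    OFFSET 0.0 10.0 0.0
    CHANNELS 3 Zrotation Xrotation Yrotation
    End Site
    {
      OFFSET 0.0 5.0 0.0
    }
  }
}
MOTION
Frames: 2
Frame Time: 0.01
1.0 2.0 3.0 10.0 20.0 30.0 5.0 -5.0 15.0
1.5 2.5 3.5 11.0 21.0 31.0 6.0 -6.0 16.0
"""


@pytest.fixture(scope="session")
def minimal_bvh() -> str:
    return MINIMAL_BVH


@pytest.fixture(scope="session")
def hierarchy():
    return synth.default_hierarchy()


@pytest.fixture(scope="session")
def template(hierarchy):
    """A 60-frame expert template for motion class 1 (quaternion-converted)."""
    return synth.make_template(1, frames=60, frame_time=0.01, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_unit_quats(rng, n: int) -> np.ndarray:
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def single_joint_motion(quats, frame_time=0.01) -> MotionSequence:
    """Wrap an (F, 4) quaternion stack as a 1-joint MotionSequence."""
    q = np.asarray(quats, dtype=float)[:, None, :]
    return MotionSequence(frame_time=frame_time, quat_frames=q)
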