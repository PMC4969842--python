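import numpy as np
import pytest

from inertrack import (
    AngleSequenceParams,
    build_arm_model,
    simulate_arm_sequence,
)


@pytest.fixture(scope="session")
def arm_model():
    return build_arm_model()


@pytest.fixture(scope="session")
def study():
    """Full noise-free study sequence: (truth trajectory, IMU dataset)."""
    return simulate_arm_sequence()


@pytest.fixture(scope="session")
def short_study(study):
    """A 160-sample slice of the study sequence for cheaper tracker tests."""
    from inertrack import IMUDataset, MotionTrajectory

    truth, data = study
    n = 160
    t = MotionTrajectory(
        truth.t[:n], truth.seg_quat[:, :n], truth.seg_pos[:, :n],
        truth.imu_quat[:, :n], truth.imu_pos[:, :n], truth.sampling_time,
    )
    d = IMUDataset(
        data.t[:n], data.gyr[:, :n], data.acc[:, :n],
        None if data.mag is None else data.mag[:, :n], data.sampling_time,
    )
    return t, d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
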