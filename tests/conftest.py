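import numpy as np
import pytest

from handscreen.synthetic import (CohortConfig, HandSkeleton, PoseParameters,
                                  build_study_cohort, forward_kinematics)


@pytest.fixture(scope="session")
def skeleton() -> HandSkeleton:
    return HandSkeleton()


@pytest.fixture()
def flat_hand(skeleton):
    """A fully extended planar right hand (all joint angles zero)."""
    pose = PoseParameters(flexion={k: 0.0 for k in PoseParameters().flexion})
    return forward_kinematics(skeleton, pose, gesture="G1")


@pytest.fixture(scope="session")
def moment_cohort():
    """The default study-shaped cohort, moment-based, fixed seed."""
    return build_study_cohort(CohortConfig(), seed=0, method="moments")
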