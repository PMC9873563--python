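"""Shared fixtures: simulated recordings and cohort tables.

Everything is generated programmatically at test time from fixed seeds; the
expensive cohort-level fixtures are session-scoped so each is built once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kinemarker as km
from kinemarker.task_features import extract_cohort_features

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


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
      OFFSET 0.0 8.0 0.0
    }
  }
}
MOTION
Frames: 3
Frame Time: 0.0166667
0 0 0 0 0 0 0 0 0
0 0 1 0 5 0 0 0 10
0 0 2 0 10 0 0 0 20
"""


@pytest.fixture(scope="session")
def gait_recording():
    rec, truth = km.simulate_gait_recording(0.3, seed=7)
    return rec, truth


@pytest.fixture(scope="session")
def gait_kin(gait_recording):
    rec, _ = gait_recording
    return km.compute_kinematics(rec)


@pytest.fixture(scope="session")
def gait_seg(gait_kin):
    return km.detect_strides(gait_kin)


@pytest.fixture(scope="session")
def peg_pair():
    rd, td = km.simulate_pegtest_recording(0.4, hand="D", seed=21)
    rn, tn = km.simulate_pegtest_recording(0.4, hand="ND", seed=22)
    return (km.compute_kinematics(rd), td), (km.compute_kinematics(rn), tn)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 18-subject study cohort, gait recordings only."""
    return km.simulate_cohort(km.SyntheticCohortSpec(seed=1), tasks=("8MW",))


@pytest.fixture(scope="session")
def gait_table(default_cohort):
    """8-MW feature table of the default cohort."""
    return extract_cohort_features(default_cohort, tasks=("8MW",))


@pytest.fixture(scope="session")
def severity_sweep():
    """Marker features over a 20-subject severity sweep (one recording each)."""
    import pandas as pd

    from kinemarker.task_features import (extract_gait_features,
                                          extract_upperbody_features)
    sev = np.linspace(0.0, 1.0, 20)
    rows = []
    for i, s in enumerate(sev):
        rec, _ = km.simulate_gait_recording(float(s), seed=500 + i)
        kin = km.compute_kinematics(rec)
        seg = km.detect_strides(kin)
        g = extract_gait_features(kin, seg).values
        rd, _ = km.simulate_pegtest_recording(float(s), hand="D", seed=600 + i)
        rn, _ = km.simulate_pegtest_recording(float(s), hand="ND", seed=700 + i)
        u = extract_upperbody_features(km.compute_kinematics(rd),
                                       km.compute_kinematics(rn)).values
        rows.append({**{f"8MW:{k}": v for k, v in g.items()},
                     **{f"9HPT:{k}": v for k, v in u.items()}})
    return sev, pd.DataFrame(rows)
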