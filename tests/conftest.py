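"""Shared fixtures: one small pelvis phantom and a modulated dual-arc plan.

Problem sizes here (80 mm body radius, 4 mm grids, 31 control points per
arc, 45 s arcs) are the package's reduced test-scale defaults; they keep
every dose calculation at a couple of seconds while preserving the
geometry the statistics are sensitive to.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vmatqa import (EngineConfig, JitterSpec, PlanSpec, compute_dose,
                    make_phantom, make_structures, make_vmat_plan)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

ARC_SECONDS = 45.0  # multiple of 0.25 s; 180 log intervals per arc


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(80.0, 120.0, 4.0)


@pytest.fixture(scope="session")
def structures(phantom):
    return make_structures(phantom, 100.0, seed=1)


@pytest.fixture(scope="session")
def fast_cfg():
    return EngineConfig(grid_spacing_mm=4.0, mu_samples=96)


@pytest.fixture(scope="session")
def demo_plan(phantom, structures, fast_cfg):
    spec = PlanSpec(control_points_per_arc=31, ptv_volume_ccm=100.0, seed=1)
    return make_vmat_plan(phantom, structures, spec, engine_cfg=fast_cfg)


@pytest.fixture(scope="session")
def demo_dose(demo_plan, phantom, fast_cfg):
    return compute_dose(demo_plan, phantom, fast_cfg)


@pytest.fixture(scope="session")
def zero_jitter():
    return JitterSpec.zero()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
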