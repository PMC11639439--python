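"""Shared phantom fixtures.

The reference femur (unit-scale template, noise off) is expensive to
voxelize, so it is built once per session and shared; tests must not
mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from femuratlas.calibration import CalibratedVolume
from femuratlas.cloud import build_cloud
from femuratlas.core import Volume
from femuratlas.frame import estimate_frame, volume_above_lt
from femuratlas.synthetic import (FemurPhantomParams, SubjectRecord,
                                  build_femur, build_geometry,
                                  make_effect_maps)


@pytest.fixture(scope="session")
def ref_params() -> FemurPhantomParams:
    return FemurPhantomParams()


@pytest.fixture(scope="session")
def ref_geometry(ref_params):
    return build_geometry(ref_params)


@pytest.fixture(scope="session")
def ref_maps(ref_params):
    return make_effect_maps(ref_params)


@pytest.fixture(scope="session")
def ref_subject() -> SubjectRecord:
    return SubjectRecord("REF", 50.0, 25.0, "female", "right")


@pytest.fixture(scope="session")
def ref_case(ref_params, ref_geometry, ref_maps, ref_subject):
    """Noise-free unit-scale case: (hu, mask, truth)."""
    return build_femur(ref_params, ref_subject, ref_maps, seed=0,
                       geometry=ref_geometry)


@pytest.fixture(scope="session")
def ref_frame(ref_case):
    hu, mask, truth = ref_case
    return estimate_frame(truth.outer_mesh, mask)


@pytest.fixture(scope="session")
def ref_cloud(ref_case, ref_frame):
    hu, mask, truth = ref_case
    return build_cloud(ref_frame, truth.outer_mesh, mask, case_id="REF")


@pytest.fixture(scope="session")
def ref_calibrated(ref_params, ref_case) -> CalibratedVolume:
    """Exact BMD volume obtained by inverting the known linear HU model."""
    hu, mask, truth = ref_case
    bmd = (hu.data - ref_params.hu_intercept) / ref_params.hu_slope
    return CalibratedVolume(Volume(bmd, hu.spacing.copy(), hu.origin.copy()),
                            mask)


@pytest.fixture(scope="session")
def ref_volume_above_lt(ref_case, ref_frame):
    hu, mask, truth = ref_case
    return volume_above_lt(mask, ref_frame.shaft_axis,
                           ref_frame.lesser_trochanter)
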