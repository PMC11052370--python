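"""Shared fixtures: phases, beams, detector geometries and ring ROIs.

The compact DXB geometry (120x120 pixels at 30 mm) keeps the Au(111) ring
fully on a small detector so rendered-movie tests stay light; the DXT
geometry is the full PILATUS-100K template at the tracking distance.
"""

import numpy as np
import pytest

from dxduo.geometry import (
    BeamSpec,
    CrystalPhase,
    DetectorGeometry,
    build_ring_roi,
    detector_template,
)


@pytest.fixture(scope="session")
def au():
    return CrystalPhase("Au", "cubic", 4.08)


@pytest.fixture(scope="session")
def zno():
    return CrystalPhase("ZnO", "hexagonal", 3.25, 5.2)


@pytest.fixture(scope="session")
def mono_beam():
    return BeamSpec(energy_keV=17.7)


@pytest.fixture(scope="session")
def pink_beam():
    return BeamSpec(energy_keV=17.7, bandwidth=0.1, mode="pink")


@pytest.fixture(scope="session")
def dxb_geom():
    return DetectorGeometry(
        pixel_pitch_mm=0.172, n_rows=120, n_cols=120,
        beam_center_px=(60.0, 60.0), distance_mm=30.0, frame_interval_s=0.1,
    )


@pytest.fixture(scope="session")
def dxt_geom():
    return detector_template(distance_mm=95.0, frame_interval_s=0.0125)


@pytest.fixture(scope="session")
def dxb_au_roi(au, mono_beam, dxb_geom):
    return build_ring_roi(au, (1, 1, 1), mono_beam, dxb_geom, half_width_px=2.0)


@pytest.fixture(scope="session")
def dxt_rois(au, zno, pink_beam, dxt_geom):
    return [
        build_ring_roi(au, (1, 1, 1), pink_beam, dxt_geom, half_width_px=2.0),
        build_ring_roi(zno, (1, 0, 0), pink_beam, dxt_geom, half_width_px=2.0),
    ]
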