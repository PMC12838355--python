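"""Shared fixtures: scaled-down acquisition profiles and quantified pools.

Tests run the generator at reduced field sizes (the physics and the
statistics are scale-free; docs/methods.md states the sizes used) so the
suite stays fast while the acceptance tests exercise the full default
geometry where the check demands it.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cytoquant as cq

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: reduced acquisition: 96 x 96 px, 9 optical sections, same voxel pitch
SMALL_ACQ = cq.AcquisitionGeometry(field_pixels=(96, 96), n_slices=9)
#: 2.2 µm cell that fits the reduced field
SMALL_GEO = cq.CellGeometry(cell_radii=(2.2, 2.2, 2.2), center_jitter=0.2)
#: even smaller profile for count-only tests
TINY_ACQ = cq.AcquisitionGeometry(field_pixels=(32, 32), n_slices=3)
TINY_GEO = cq.CellGeometry(cell_radii=(0.8, 0.8, 0.8), center_jitter=0.05)

NOISELESS = cq.IntensityModel(noise_sigma=0.0, psf_sigma=0.0)


@pytest.fixture(scope="session")
def small_acq() -> cq.AcquisitionGeometry:
    return SMALL_ACQ


@pytest.fixture(scope="session")
def small_geo() -> cq.CellGeometry:
    return SMALL_GEO


def make_cells(n, intensity, geometry=SMALL_GEO, acq=SMALL_ACQ, seed=0):
    """Render and quantify n independent cells; returns (records frame,
    list of (stack, truth))."""
    rng = np.random.default_rng(seed)
    records, raw = [], []
    for i in range(n):
        s = int(rng.integers(0, 2**31))
        stack, truth = cq.generate_cell_stack(
            geometry, intensity, acq, seed=s, stack_id=f"cell{i}"
        )
        records.append(cq.quantify_cell(stack, labels={"cell_id": f"cell{i}"}))
        raw.append((stack, truth))
    return cq.records_to_frame(records), raw


@pytest.fixture(scope="session")
def null_pool():
    """480 quantified cells from one null condition (shared by the
    calibration tests)."""
    frame, _ = make_cells(480, cq.IntensityModel(), seed=1234)
    return frame
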