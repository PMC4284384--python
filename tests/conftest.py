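"""Shared fixtures: small synthetic fields generated at test time."""

import numpy as np
import pytest

from endokin.segmentation import SegmentationParams, segment_frame
from endokin.synthetic import (
    AcquisitionSpec,
    CellSpec,
    KineticsSpec,
    simulate_series,
)

LN2 = float(np.log(2.0))


@pytest.fixture(scope="session")
def single_cell_noiseless():
    """One round radius-14 cell, noiseless, 4 time points (T1/2 = 34 min)."""
    cell = CellSpec(center=(70.0, 70.0), radius_px=14.0)
    kin = KineticsSpec(k_int_true=LN2 / 34.0)
    acq = AcquisitionSpec(
        frame_shape=(141, 141), time_points=(0, 30, 60, 120),
        noise_model="none", rng_seed=7,
    )
    series, truth = simulate_series([cell], kin, acq)
    return series, truth, kin, acq


@pytest.fixture(scope="session")
def small_field():
    """Nine noiseless round cells on a 300x300 frame, 5 time points."""
    rng = np.random.default_rng(11)
    centers = [(60 + 90 * i, 60 + 90 * j) for i in range(3) for j in range(3)]
    cells = [
        CellSpec(center=(r + rng.uniform(-5, 5), c + rng.uniform(-5, 5)),
                 radius_px=float(rng.uniform(13, 15)))
        for r, c in centers
    ]
    kin = KineticsSpec(k_int_true=LN2 / 30.0)
    acq = AcquisitionSpec(
        frame_shape=(300, 300), time_points=(0, 20, 40, 80, 160),
        noise_model="none", rng_seed=3,
    )
    series, truth = simulate_series(cells, kin, acq)
    return series, truth, kin, acq


@pytest.fixture(scope="session")
def small_field_segmented(small_field):
    series, truth, kin, acq = small_field
    cells, regions = segment_frame(series.frame("reference", 0), SegmentationParams())
    return series, truth, cells, regions
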