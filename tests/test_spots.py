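"""Spot detection/classification/integration against analytic constructions."""

import dataclasses

import numpy as np
import pytest

from endokin.segmentation import SegmentationParams, segment_frame
from endokin.spots import (
    ACCEPTED,
    REJ_BOTH,
    REJ_CON,
    REJ_INT,
    REJ_SIZE,
    STATUSES,
    SpotParams,
    SpotRecord,
    classify_spots,
    detect_spots,
    integrate_signals,
    quantify_frame,
)
from endokin.synthetic import (
    AcquisitionSpec,
    CellSpec,
    KineticsSpec,
    simulate_series,
)


def _segmented_disk(shape=(101, 101), center=(50, 50), radius=16.0):
    """A single segmented round cell to host constructed spots."""
    cell = CellSpec(center=center, radius_px=radius)
    kin = KineticsSpec(k_int_true=0.0, s0_frac=0.0, smax_frac=0.0,
                       n_spots_membrane=1, n_spots_cytoplasm=1)
    acq = AcquisitionSpec(frame_shape=shape, time_points=(0.0,), noise_model="none")
    series, _ = simulate_series([cell], kin, acq)
    cells, regions = segment_frame(series.frame("reference", 0),
                                   SegmentationParams())
    return cells, regions


def _gauss(shape, r0, c0, amplitude, sigma, background):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    )


class TestDetect:
    def test_uniform_frame_no_candidates(self):
        _, regions = _segmented_disk()
        frame = np.full((101, 101), 50.0)
        assert detect_spots(frame, regions, SpotParams()) == []

    def test_single_gaussian_in_cytoplasm(self):
        _, regions = _segmented_disk()
        frame = _gauss((101, 101), 50, 50, amplitude=500, sigma=1.2, background=50)
        cands = detect_spots(frame, regions, SpotParams())
        assert len(cands) == 1
        spot = cands[0]
        assert spot.region_assignment == "cytoplasm"
        assert spot.peak_rc == (50, 50)
        assert spot.contrast == pytest.approx(10.0, rel=0.05)
        # aperture integration recovers the analytic mass 2*pi*sigma^2*A
        assert spot.integrated_intensity == pytest.approx(
            2 * np.pi * 1.2**2 * 500, rel=0.05
        )

    def test_spot_outside_regions_excluded(self):
        _, regions = _segmented_disk()
        frame = _gauss((101, 101), 5, 5, amplitude=500, sigma=1.2, background=50)
        assert detect_spots(frame, regions, SpotParams()) == []

    def test_shape_mismatch_error(self):
        _, regions = _segmented_disk()
        with pytest.raises(ValueError, match="mismatch"):
            detect_spots(np.zeros((50, 50)), regions, SpotParams())

    def test_well_separated_spots_oracle(self):
        """Peaks within 1 px and intensities within 5% on a known field."""
        _, regions = _segmented_disk(shape=(161, 161), center=(80, 80), radius=35.0)
        truth = [(68, 80, 400), (80, 64, 700), (92, 92, 250), (80, 96, 550)]
        frame = np.full((161, 161), 50.0)
        for r0, c0, amp in truth:
            frame += _gauss((161, 161), r0, c0, amp, 1.2, 0.0)
        cands = detect_spots(frame, regions, SpotParams())
        assert len(cands) == len(truth)
        for r0, c0, amp in truth:
            match = min(cands, key=lambda s: np.hypot(s.peak_rc[0] - r0,
                                                      s.peak_rc[1] - c0))
            assert np.hypot(match.peak_rc[0] - r0, match.peak_rc[1] - c0) <= 1
            assert match.integrated_intensity == pytest.approx(
                2 * np.pi * 1.2**2 * amp, rel=0.05
            )


def _mk(status_metrics):
    """Candidate records from (peak, contrast, size) triples."""
    return [
        SpotRecord(
            peak_rc=(i, i), cell_label=1, region_assignment="membrane",
            peak_intensity=p, integrated_intensity=p * 9.0, contrast=c,
            size_px=s, local_background=50.0,
        )
        for i, (p, c, s) in enumerate(status_metrics)
    ]


class TestClassify:
    def test_status_enumeration(self):
        params = SpotParams(min_intensity=100, min_contrast=1.0,
                            min_size_px=2, max_size_px=50)
        cands = _mk([
            (500, 5.0, 9), (500, 5.0, 9), (500, 5.0, 9),  # pass all
            (50, 5.0, 9),    # fails intensity only
            (500, 0.5, 9),   # fails contrast only
            (50, 0.5, 9),    # fails both
            (500, 5.0, 1),   # too small
        ])
        statuses = [s.status for s in classify_spots(cands, params)]
        assert statuses == [ACCEPTED] * 3 + [REJ_INT, REJ_CON, REJ_BOTH, REJ_SIZE]

    def test_permissive_params_accept_all(self):
        params = SpotParams(min_intensity=0, min_contrast=0,
                            min_size_px=0, max_size_px=10**9)
        cands = _mk([(1, 0.01, 3), (1000, 50, 40)])
        assert all(s.status == ACCEPTED for s in classify_spots(cands, params))

    def test_size_rejection_trumps_intensity(self):
        params = SpotParams(min_intensity=100, min_contrast=1.0, min_size_px=5)
        (rec,) = classify_spots(_mk([(10_000, 99.0, 2)]), params)
        assert rec.status == REJ_SIZE

    def test_every_candidate_gets_exactly_one_status(self):
        rng = np.random.default_rng(0)
        cands = _mk([(rng.uniform(0, 1000), rng.uniform(0, 10),
                      rng.integers(1, 30)) for _ in range(50)])
        params = SpotParams(min_intensity=200, min_contrast=2.0,
                            min_size_px=3, max_size_px=20)
        statused = classify_spots(cands, params)
        assert len(statused) == 50
        assert all(s.status in STATUSES for s in statused)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        cands = _mk([(rng.uniform(0, 1000), rng.uniform(0, 10), 5)
                     for _ in range(80)])
        def n_accepted(mi, mc):
            params = SpotParams(min_intensity=mi, min_contrast=mc)
            return sum(s.status == ACCEPTED for s in classify_spots(cands, params))
        for lo, hi in [(0, 100), (100, 500), (500, 900)]:
            assert n_accepted(hi, 1.0) <= n_accepted(lo, 1.0)
            assert n_accepted(100, hi / 100) <= n_accepted(100, lo / 100)


class TestIntegrate:
    def test_no_accepted_spots_zero_signals(self, small_field_segmented):
        _, _, _, regions = small_field_segmented
        sig = integrate_signals([], regions, well="w", time_min=0.0)
        assert sig.membrane_signal == 0 and sig.cytoplasm_signal == 0

    def test_arithmetic_oracle(self):
        regions = _FakeRegions(membrane=500, cytoplasm=400)
        spots = [
            _spot("membrane", 100.0, ACCEPTED),
            _spot("membrane", 50.0, ACCEPTED),
            _spot("membrane", 999.0, REJ_INT),  # rejected: not counted
            _spot("cytoplasm", 200.0, ACCEPTED),
        ]
        sig = integrate_signals(spots, [regions])
        assert sig.membrane_signal == pytest.approx(150.0 / 500)
        assert sig.cytoplasm_signal == pytest.approx(200.0 / 400)

    def test_pooling_two_fields(self):
        ra = _FakeRegions(membrane=500, cytoplasm=400)
        rb = _FakeRegions(membrane=1000, cytoplasm=800)
        spots = {
            "f1": [_spot("membrane", 100.0, ACCEPTED)],
            "f2": [_spot("membrane", 200.0, ACCEPTED)],
        }
        sig = integrate_signals([], {"f1": [ra], "f2": [rb]},
                                spots_by_field=spots)
        assert sig.membrane_signal == pytest.approx(300.0 / 1500)

    def test_zero_area_error(self):
        with pytest.raises(ValueError, match="zero total region area"):
            integrate_signals([], [])


def _spot(region, intensity, status):
    return SpotRecord(
        peak_rc=(0, 0), cell_label=1, region_assignment=region,
        peak_intensity=intensity, integrated_intensity=intensity,
        contrast=1.0, size_px=5, local_background=50.0, status=status,
    )


class _FakeRegions:
    def __init__(self, membrane, cytoplasm):
        self.membrane_area_px = membrane
        self.cytoplasm_area_px = cytoplasm


def test_recovered_time_course_tracks_kinetic_law(small_field_segmented):
    """Noiseless pipeline fraction within 0.05 of truth at every time point."""
    series, truth, _, regions = small_field_segmented
    kin_truth = truth.cell_table.drop_duplicates("time_min").set_index("time_min")
    for ti, t in enumerate(series.times_min):
        sig, _ = quantify_frame(series.frame("signal", ti), regions,
                                SpotParams(), time_min=t)
        measured = sig.cytoplasm_signal / (sig.cytoplasm_signal + sig.membrane_signal)
        assert measured == pytest.approx(
            kin_truth.loc[t, "cytoplasm_fraction"], abs=0.05
        )
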