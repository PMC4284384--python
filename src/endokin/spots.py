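"""Fluorescent-spot detection, qualification and per-area signal integration.

Receptor-drug complexes cluster into compact bright spots; the algorithm
detects candidate spots in the drug-signal channel inside each cell's
membrane-or-cytoplasm search region, accepts or rejects each candidate on
intensity, contrast and size, and integrates accepted-spot intensity per unit
region area:

    membrane_signal  = sum(accepted membrane spot intensities) / sum(membrane areas)
    cytoplasm_signal = likewise for cytoplasm regions

pooling all fields of a well.  Detection is a difference-of-Gaussians
band-pass followed by local-maxima extraction; contrast is defined as
(peak - local background) / local background with the local background taken
as the median intensity in an annulus around the spot.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .segmentation import RegionSet

__all__ = [
    "SpotParams",
    "SpotRecord",
    "RegionSignal",
    "detect_spots",
    "classify_spots",
    "integrate_signals",
    "spots_to_frame",
    "quantify_frame",
]

MEMBRANE = "membrane"
CYTOPLASM = "cytoplasm"

ACCEPTED = "accepted"
REJ_INT = "rejected_intensity"
REJ_CON = "rejected_contrast"
REJ_BOTH = "rejected_both"
REJ_SIZE = "rejected_size"
STATUSES = (ACCEPTED, REJ_INT, REJ_CON, REJ_BOTH, REJ_SIZE)


@dataclass(frozen=True)
class SpotParams:
    """Spot qualification thresholds and detection scale.

    ``min_intensity`` applies to the background-subtracted peak amplitude when
    ``intensity_mode="peak"``, or to the integrated background-subtracted
    intensity when ``"integrated"``.  ``detection_scale_px`` is the expected
    spot Gaussian radius; the integration aperture is
    ``aperture_factor * detection_scale_px``.
    """

    min_intensity: float = 10.0
    intensity_mode: str = "peak"  # "peak" | "integrated"
    min_contrast: float = 0.1
    min_size_px: int = 1
    max_size_px: int = 200
    detection_scale_px: float = 1.2
    aperture_factor: float = 3.0
    bg_annulus_px: tuple[float, float] = (5.0, 8.0)  # local-background radii

    def __post_init__(self):
        if self.min_size_px > self.max_size_px:
            raise ValueError("min_size_px must be <= max_size_px")
        if self.min_contrast < 0:
            raise ValueError("min_contrast must be >= 0")
        if self.intensity_mode not in ("peak", "integrated"):
            raise ValueError(f"unknown intensity_mode {self.intensity_mode!r}")


@dataclass
class SpotRecord:
    """One detected spot with its metrics and accept/reject status."""

    peak_rc: tuple[int, int]
    cell_label: int
    region_assignment: str  # "membrane" | "cytoplasm" | "none"
    peak_intensity: float  # background-subtracted peak amplitude (AFU)
    integrated_intensity: float  # background-subtracted aperture sum (AFU)
    contrast: float
    size_px: int
    local_background: float
    status: str = "candidate"


@dataclass
class RegionSignal:
    """Area-normalized membrane/cytoplasm signal for one well at one time."""

    well: str
    time_min: float
    membrane_signal: float  # AFU per px
    cytoplasm_signal: float
    n_cells: int
    n_spots_membrane: int
    n_spots_cytoplasm: int
    membrane_area_px: int = 0
    cytoplasm_area_px: int = 0


def _region_maps(regions: list[RegionSet], shape) -> tuple[np.ndarray, np.ndarray]:
    """Label maps (0 = none) of membrane and cytoplasm pixels of all cells."""
    mem = np.zeros(shape, dtype=np.int32)
    cyt = np.zeros(shape, dtype=np.int32)
    for rs in regions:
        mem[rs.membrane_region] = rs.label
        cyt[rs.cytoplasm_region] = rs.label
    return mem, cyt


def _annulus_offsets(r_in: float, r_out: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(math.ceil(r_out))
    rr, cc = np.mgrid[-n : n + 1, -n : n + 1]
    d = np.hypot(rr, cc)
    sel = (d >= r_in) & (d <= r_out)
    return rr[sel], cc[sel]


def detect_spots(
    signal_frame: np.ndarray,
    regions: list[RegionSet],
    params: SpotParams,
) -> list[SpotRecord]:
    """Find candidate spots inside the cells' search regions.

    Band-pass (difference-of-Gaussians at the detection scale) local maxima,
    restricted to membrane-or-cytoplasm pixels; each candidate carries its
    background-subtracted peak and integrated intensity, contrast, size and
    region assignment (by peak-pixel membership).
    """
    frame = np.asarray(signal_frame, dtype=float)
    if regions and regions[0].membrane_region.shape != frame.shape:
        raise ValueError("signal frame and regions have mismatched shapes")
    if not regions:
        return []
    mem_map, cyt_map = _region_maps(regions, frame.shape)
    search = (mem_map > 0) | (cyt_map > 0)
    # camera background: robust level of pixels outside every search region;
    # used for intensity integration (the local annulus median only defines
    # contrast, since in crowded regions it also sees neighboring structure)
    outside = ~search
    frame_bg = float(np.median(frame[outside])) if outside.any() else 0.0
    sigma = params.detection_scale_px
    band = difference_of_gaussians(frame, low_sigma=sigma / 1.6, high_sigma=sigma * 1.6)
    min_dist = max(1, int(round(params.detection_scale_px)))
    coords = peak_local_max(
        band,
        min_distance=min_dist,
        threshold_abs=1e-9,
        labels=search.astype(np.int32),
        exclude_border=False,
    )
    off_r, off_c = _annulus_offsets(*params.bg_annulus_px)
    ap_r = params.aperture_factor * params.detection_scale_px
    ap_off_r, ap_off_c = _disk_offsets(ap_r)
    h, w = frame.shape
    # Voronoi-restricted apertures: a pixel inside several overlapping
    # apertures contributes only to its nearest peak, so crowded spots
    # partition the signal instead of double-counting shared pixels
    tree = cKDTree(coords) if len(coords) else None
    records: list[SpotRecord] = []
    for idx, (r, c) in enumerate(coords):
        rr = np.clip(r + off_r, 0, h - 1)
        cc = np.clip(c + off_c, 0, w - 1)
        local_bg = float(np.median(frame[rr, cc]))
        peak_raw = float(frame[r, c])
        amp = peak_raw - frame_bg
        if amp <= 0:
            continue
        if local_bg <= 0:
            warnings.warn(
                f"non-positive local background at {(r, c)}; contrast set to inf",
                stacklevel=2,
            )
            contrast = float("inf")
        else:
            contrast = max(peak_raw - local_bg, 0.0) / local_bg
        # integrated intensity: camera-background-subtracted sum over the
        # aperture pixels owned by this peak
        arr = np.clip(r + ap_off_r, 0, h - 1)
        acc = np.clip(c + ap_off_c, 0, w - 1)
        pix = np.column_stack([arr, acc])
        _, owner = tree.query(pix, k=1)
        own = owner == idx
        integrated = float(np.sum(frame[arr[own], acc[own]] - frame_bg))
        size = _halfpeak_size(frame, r, c, frame_bg, amp)
        label = int(mem_map[r, c]) or int(cyt_map[r, c])
        if mem_map[r, c]:
            region = MEMBRANE
        elif cyt_map[r, c]:
            region = CYTOPLASM
        else:  # unreachable given the search restriction; kept for safety
            region = "none"
        records.append(
            SpotRecord(
                peak_rc=(int(r), int(c)),
                cell_label=label,
                region_assignment=region,
                peak_intensity=amp,
                integrated_intensity=integrated,
                contrast=contrast,
                size_px=size,
                local_background=local_bg,
            )
        )
    return records


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(math.ceil(radius))
    rr, cc = np.mgrid[-n : n + 1, -n : n + 1]
    sel = np.hypot(rr, cc) <= radius
    return rr[sel], cc[sel]


def _halfpeak_size(frame, r, c, local_bg, amp) -> int:
    """Size = connected pixel count above half of the bg-subtracted peak."""
    half = 8
    h, w = frame.shape
    lo_r, hi_r = max(0, r - half), min(h, r + half + 1)
    lo_c, hi_c = max(0, c - half), min(w, c + half + 1)
    win = frame[lo_r:hi_r, lo_c:hi_c] - local_bg
    above = win >= amp / 2.0
    lab, _ = ndi.label(above)
    own = lab[r - lo_r, c - lo_c]
    if own == 0:
        return 1
    return int((lab == own).sum())


def classify_spots(candidates: list[SpotRecord], params: SpotParams) -> list[SpotRecord]:
    """Assign accept/reject status to every candidate.

    Size is checked independently first; among size-qualified spots the four
    intensity/contrast codes apply: accepted, rejected_intensity,
    rejected_contrast, rejected_both.
    """
    out = []
    for rec in candidates:
        if not (params.min_size_px <= rec.size_px <= params.max_size_px):
            status = REJ_SIZE
        else:
            value = (
                rec.peak_intensity
                if params.intensity_mode == "peak"
                else rec.integrated_intensity
            )
            fail_int = value < params.min_intensity
            fail_con = rec.contrast < params.min_contrast
            if fail_int and fail_con:
                status = REJ_BOTH
            elif fail_int:
                status = REJ_INT
            elif fail_con:
                status = REJ_CON
            else:
                status = ACCEPTED
        out.append(dataclasses.replace(rec, status=status))
    return out


def integrate_signals(
    statused: list[SpotRecord],
    regions_by_field: dict[str, list[RegionSet]] | list[RegionSet],
    well: str = "",
    time_min: float = 0.0,
    spots_by_field: dict[str, list[SpotRecord]] | None = None,
) -> RegionSignal:
    """Pool accepted-spot intensity over all fields of a well, per unit area.

    Either pass a flat spot list with a single field's regions, or
    ``spots_by_field``/``regions_by_field`` dicts keyed by field id; sums of
    intensities and of region areas are pooled before division.
    """
    if isinstance(regions_by_field, dict):
        region_lists = regions_by_field
        spot_lists = spots_by_field if spots_by_field is not None else {"": statused}
    else:
        region_lists = {"": regions_by_field}
        spot_lists = {"": statused}
    mem_area = sum(rs.membrane_area_px for lst in region_lists.values() for rs in lst)
    cyt_area = sum(rs.cytoplasm_area_px for lst in region_lists.values() for rs in lst)
    n_cells = sum(len(lst) for lst in region_lists.values())
    if mem_area == 0 or cyt_area == 0:
        raise ValueError("zero total region area: no cells to quantify")
    mem_sum = cyt_sum = 0.0
    n_mem = n_cyt = 0
    for lst in spot_lists.values():
        for rec in lst:
            if rec.status != ACCEPTED:
                continue
            if rec.region_assignment == MEMBRANE:
                mem_sum += rec.integrated_intensity
                n_mem += 1
            elif rec.region_assignment == CYTOPLASM:
                cyt_sum += rec.integrated_intensity
                n_cyt += 1
    return RegionSignal(
        well=well,
        time_min=float(time_min),
        membrane_signal=mem_sum / mem_area,
        cytoplasm_signal=cyt_sum / cyt_area,
        n_cells=n_cells,
        n_spots_membrane=n_mem,
        n_spots_cytoplasm=n_cyt,
        membrane_area_px=mem_area,
        cytoplasm_area_px=cyt_area,
    )


def spots_to_frame(spots: list[SpotRecord]) -> pd.DataFrame:
    """Tabulate spot records (one row per spot) for CSV output."""
    return pd.DataFrame(
        [
            dict(
                row=s.peak_rc[0], col=s.peak_rc[1], cell_label=s.cell_label,
                region=s.region_assignment, peak_intensity=s.peak_intensity,
                integrated_intensity=s.integrated_intensity, contrast=s.contrast,
                size_px=s.size_px, local_background=s.local_background,
                status=s.status,
            )
            for s in spots
        ],
        columns=[
            "row", "col", "cell_label", "region", "peak_intensity",
            "integrated_intensity", "contrast", "size_px", "local_background",
            "status",
        ],
    )


def quantify_frame(
    signal_frame: np.ndarray,
    regions: list[RegionSet],
    params: SpotParams,
    well: str = "",
    time_min: float = 0.0,
) -> tuple[RegionSignal, list[SpotRecord]]:
    """Detect, classify and integrate one frame; returns (signal, spots)."""
    cands = detect_spots(signal_frame, regions, params)
    statused = classify_spots(cands, params)
    return integrate_signals(statused, regions, well=well, time_min=time_min), statused
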