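"""Cell segmentation and membrane/cytoplasm region construction.

Implements the first half of the image-analysis algorithm: a global intensity
threshold on the cytoplasm-dye (reference) channel yields the initial mask;
connected foreground is segmented into cell objects (optionally splitting
touching cells at the distance-transform watershed line); and each object is
surrounded by a membrane band extending a configurable number of pixels in and
out of its boundary, the remaining interior being the cytoplasm region.
Handles both round (suspension) and irregular (adherent) outlines, and
optional gating of cells on a co-registered marker channel (e.g. retaining
only the marker-positive minority of a mixed population).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import clear_border, watershed

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "Mask",
    "CellObject",
    "RegionSet",
    "build_initial_mask",
    "segment_cells",
    "build_regions",
    "build_all_regions",
    "gate_by_marker",
    "segment_frame",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation stage.

    ``threshold_mode`` selects how the reference-channel threshold is resolved:
    ``"otsu"`` (automatic global, the default), ``"fixed"`` (use
    ``threshold_value`` as an absolute intensity) or ``"percentile"`` (use it
    as a percentile of the frame's intensities).  ``ring_out_px`` /
    ``ring_in_px`` set how far the membrane band extends outside / inside the
    object boundary.
    """

    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    min_area_px: int = 60
    max_area_px: int = 100_000
    split_touching: bool = True
    ring_out_px: int = 2
    ring_in_px: int = 2
    exclude_border: bool = True
    marker_gate: tuple[str, float] | None = None  # (channel role, min mean intensity)

    def __post_init__(self):
        if self.threshold_mode not in ("otsu", "fixed", "percentile"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode in ("fixed", "percentile") and self.threshold_value is None:
            raise ValueError(f"threshold_mode {self.threshold_mode!r} needs threshold_value")
        if self.ring_out_px < 0 or self.ring_in_px < 0:
            raise ValueError("ring widths must be nonnegative")
        if self.ring_out_px + self.ring_in_px < 1:
            raise ValueError("ring_out_px + ring_in_px must be >= 1")
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")


@dataclass
class Mask:
    """Binary foreground mask plus the threshold that produced it."""

    data: np.ndarray
    threshold: float
    mode: str


@dataclass
class CellObject:
    """One segmented cell: its pixels, boundary and shape diagnostics."""

    label: int
    pixels: np.ndarray  # boolean mask, frame shape
    boundary: np.ndarray  # boolean mask of inner-boundary pixels
    centroid: tuple[float, float]
    area_px: int
    equivalent_radius_px: float
    eccentricity: float


@dataclass
class RegionSet:
    """Membrane and cytoplasm search regions of one cell."""

    label: int
    membrane_region: np.ndarray  # boolean mask
    cytoplasm_region: np.ndarray
    membrane_area_px: int
    cytoplasm_area_px: int


def resolve_threshold(frame: np.ndarray, params: SegmentationParams) -> float:
    if params.threshold_mode == "fixed":
        return float(params.threshold_value)
    if params.threshold_mode == "percentile":
        return float(np.percentile(frame, params.threshold_value))
    if np.ptp(frame) == 0:
        # flat frame: no automatic threshold exists; everything is background
        warnings.warn("flat reference frame; returning empty mask", stacklevel=2)
        return float(frame.max()) + 1.0
    return float(threshold_otsu(frame))


def build_initial_mask(reference_frame: np.ndarray, params: SegmentationParams) -> Mask:
    """Threshold the reference channel: mask is true where intensity >= threshold."""
    frame = np.asarray(reference_frame)
    if frame.ndim != 2:
        raise ValueError("reference_frame must be a single-channel 2-D array")
    thr = resolve_threshold(frame, params)
    mask = frame >= thr
    if not mask.any():
        warnings.warn("initial mask is empty (all-background frame)", stacklevel=2)
    logger.debug("threshold=%.3f mode=%s foreground=%d px", thr, params.threshold_mode, mask.sum())
    return Mask(data=mask, threshold=thr, mode=params.threshold_mode)


def _split_watershed(mask: np.ndarray) -> np.ndarray:
    """Split touching convex blobs at the distance-transform watershed line."""
    dist = ndi.distance_transform_edt(mask)
    # seeds at smoothed distance maxima; min separation tied to typical radius
    smooth = ndi.gaussian_filter(dist, sigma=2.0)
    coords = peak_local_max(
        smooth, min_distance=7, labels=mask, exclude_border=False
    )
    seeds = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        return ndi.label(mask)[0]
    return watershed(-dist, markers=seeds, mask=mask)


def segment_cells(mask: Mask | np.ndarray, params: SegmentationParams) -> list[CellObject]:
    """Segment the foreground mask into cell objects.

    Objects outside ``[min_area_px, max_area_px]`` are discarded; border
    touchers are discarded when ``exclude_border``; labels are reassigned in
    raster order of the object centroid so output is deterministic.
    """
    data = mask.data if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    if not data.any():
        return []
    if params.split_touching:
        labels = _split_watershed(data)
    else:
        labels = ndi.label(data)[0]
    if params.exclude_border:
        labels = clear_border(labels)
    props = regionprops(labels)
    keep = [p for p in props if params.min_area_px <= p.area <= params.max_area_px]
    # raster order of centroid (row, then col) for deterministic labeling
    keep.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    cells: list[CellObject] = []
    for new_label, p in enumerate(keep, start=1):
        pix = labels == p.label
        eroded = ndi.binary_erosion(pix, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
        boundary = pix & ~eroded
        cells.append(
            CellObject(
                label=new_label,
                pixels=pix,
                boundary=boundary,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                area_px=int(p.area),
                equivalent_radius_px=float(np.sqrt(p.area / np.pi)),
                eccentricity=float(p.eccentricity),
            )
        )
    return cells


def build_regions(cell: CellObject, params: SegmentationParams) -> RegionSet:
    """Build the membrane band and cytoplasm region of a single cell.

    Membrane = pixels whose Euclidean distance to the cell's boundary pixel
    set is <= ring_out_px (outside the object) or <= ring_in_px (inside);
    cytoplasm = object pixels not in the membrane band.  Use
    :func:`build_all_regions` when neighboring cells may contest exterior
    pixels.
    """
    return build_all_regions([cell], params)[0]


def build_all_regions(
    cells: list[CellObject], params: SegmentationParams
) -> list[RegionSet]:
    """Build regions for all cells, resolving exterior-pixel contests.

    Exterior pixels claimed by two membrane bands are assigned to the nearer
    boundary; ties go to the lower label.  Cells whose cytoplasm would be
    empty are flagged (empty cytoplasm region) — callers should drop them from
    kinetic quantification.
    """
    if not cells:
        return []
    shape = cells[0].pixels.shape
    # claim map over exterior pixels: (best distance, owning label)
    best_dist = np.full(shape, np.inf)
    owner = np.zeros(shape, dtype=np.int32)
    per_cell: list[dict] = []
    for cell in cells:
        dist_to_boundary = ndi.distance_transform_edt(~cell.boundary)
        inner_mem = cell.pixels & (dist_to_boundary <= params.ring_in_px)
        outer_candidate = (~cell.pixels) & (dist_to_boundary <= params.ring_out_px)
        per_cell.append(dict(cell=cell, inner=inner_mem, outer=outer_candidate,
                             dist=dist_to_boundary))
        upd = outer_candidate & (dist_to_boundary < best_dist)
        # ties: strictly-less keeps the earlier (lower) label
        best_dist[upd] = dist_to_boundary[upd]
        owner[upd] = cell.label
    occupied = np.zeros(shape, dtype=bool)
    for pc in per_cell:
        occupied |= pc["cell"].pixels
    results: list[RegionSet] = []
    n_empty = 0
    for pc in per_cell:
        cell = pc["cell"]
        outer = pc["outer"] & (owner == cell.label) & ~occupied
        membrane = pc["inner"] | outer
        cytoplasm = cell.pixels & ~membrane
        if not cytoplasm.any():
            n_empty += 1
        results.append(
            RegionSet(
                label=cell.label,
                membrane_region=membrane,
                cytoplasm_region=cytoplasm,
                membrane_area_px=int(membrane.sum()),
                cytoplasm_area_px=int(cytoplasm.sum()),
            )
        )
    if n_empty:
        warnings.warn(
            f"{n_empty} cell(s) have an empty cytoplasm region and should be "
            "excluded from kinetics", stacklevel=2,
        )
    return results


def gate_by_marker(
    cells: list[CellObject],
    marker_frame: np.ndarray | None,
    gate: tuple[str, float] | float | None,
) -> list[CellObject]:
    """Retain cells whose mean marker intensity >= the gate threshold."""
    if gate is None:
        return list(cells)
    threshold = gate[1] if isinstance(gate, tuple) else float(gate)
    if marker_frame is None:
        raise ValueError("marker gate configured but no marker channel supplied")
    marker = np.asarray(marker_frame)
    kept = []
    for cell in cells:
        mean_int = float(marker[cell.pixels].mean())
        decision = mean_int >= threshold
        logger.debug("cell %d marker mean %.2f -> %s", cell.label, mean_int,
                     "keep" if decision else "drop")
        if decision:
            kept.append(cell)
    if not kept:
        warnings.warn("marker gate removed every cell", stacklevel=2)
    return kept


def segment_frame(
    reference_frame: np.ndarray,
    params: SegmentationParams,
    marker_frame: np.ndarray | None = None,
) -> tuple[list[CellObject], list[RegionSet]]:
    """Convenience wrapper: mask -> objects -> (optional gate) -> regions."""
    mask = build_initial_mask(reference_frame, params)
    cells = segment_cells(mask, params)
    if params.marker_gate is not None:
        cells = gate_by_marker(cells, marker_frame, params.marker_gate)
    regions = build_all_regions(cells, params)
    # drop cells whose cytoplasm came out empty
    keep = [r.cytoplasm_area_px > 0 for r in regions]
    cells = [c for c, k in zip(cells, keep) if k]
    regions = [r for r, k in zip(regions, keep) if k]
    return cells, regions
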