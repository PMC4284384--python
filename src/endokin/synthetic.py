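"""Seeded synthetic two-channel live-cell time-lapse generator with ground truth.

Emulates the experimental systems used to measure receptor-mediated
internalization of fluorescently tagged biopharmaceuticals: a cytoplasmic
reference dye (e.g. CFSE) filling each cell body in one channel, and the
drug-associated signal in a second channel appearing as compact fluorescent
spots that translocate from a membrane annulus into the cytoplasm with
first-order kinetics,

    cytoplasm_fraction(t) = s0 + (1 - exp(-k_int * t)) * smax.

Cells are static across frames (the same group of cells is monitored over the
whole time course); receptor clusters (spots) keep fixed positions and
relative weights, and only their amplitudes redistribute between the membrane
and cytoplasm compartments as internalization proceeds.  Every rendered spot
kernel is normalized to unit discrete sum, so total signal above background is
conserved exactly (floating point) when photobleaching is off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CellSpec",
    "KineticsSpec",
    "AcquisitionSpec",
    "GroundTruth",
    "ImageSeries",
    "FieldLayout",
    "Preset",
    "FieldOverlapError",
    "cytoplasm_fraction",
    "make_layout",
    "render_field",
    "simulate_series",
    "make_preset",
    "write_series",
    "PRESET_NAMES",
]

# Half-width (px) of the membrane annulus straddling the true cell boundary in
# which membrane-compartment spots are centered.
MEMBRANE_ANNULUS_HALF_PX = 2.0


class FieldOverlapError(ValueError):
    """Raised when generated cells overlap beyond the configured tolerance."""


def cytoplasm_fraction(t_min, k_int, s0_frac, smax_frac):
    """Closed-form true cytoplasmic signal fraction at time ``t_min`` (minutes)."""
    t = np.asarray(t_min, dtype=float)
    return s0_frac + (1.0 - np.exp(-k_int * t)) * smax_frac


@dataclass(frozen=True)
class CellSpec:
    """Geometry and brightness of one synthetic cell."""

    center: tuple[float, float]  # (row, col), px
    radius_px: float
    morphology: str = "round"  # "round" | "irregular"
    boundary_jitter: float = 0.0  # relative radial amplitude for irregular outlines
    reference_intensity: float = 300.0  # AFU, cytoplasm dye fill
    signal_total: float = 50_000.0  # AFU, total drug-tag intensity on this cell
    marker_positive: bool = False

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")
        if self.signal_total < 0:
            raise ValueError("signal_total must be >= 0")
        if self.morphology not in ("round", "irregular"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if not 0 <= self.boundary_jitter < 0.5:
            # star-convex outlines with |dr|/r < 0.5 cannot self-intersect
            raise ValueError("boundary_jitter must be in [0, 0.5)")


@dataclass(frozen=True)
class KineticsSpec:
    """Ground-truth internalization kinetics shared by all cells of a field."""

    k_int_true: float  # 1/min
    s0_frac: float = 0.1
    smax_frac: float = 0.8
    n_spots_membrane: int = 12
    n_spots_cytoplasm: int = 10
    spot_sigma_px: float = 1.2

    def __post_init__(self):
        if self.k_int_true < 0:
            raise ValueError("k_int_true must be >= 0")
        if self.s0_frac < 0 or self.smax_frac < 0:
            raise ValueError("fractions must be >= 0")
        if self.s0_frac + self.smax_frac > 1 + 1e-12:
            raise ValueError("s0_frac + smax_frac must be <= 1")

    def cytoplasm_fraction(self, t_min):
        return cytoplasm_fraction(t_min, self.k_int_true, self.s0_frac, self.smax_frac)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging conditions: frame geometry, time grid, background and noise."""

    frame_shape: tuple[int, int] = (512, 512)
    time_points: tuple[float, ...] = (0, 30, 60, 90, 120, 150, 180)  # minutes
    background_level: float = 50.0  # AFU
    noise_model: str = "poisson"  # "none" | "gaussian" | "poisson"
    gaussian_sigma: float = 3.0  # read-noise sd (AFU); also used for "gaussian"
    photobleach_rate: float = 0.0  # 1/min
    rng_seed: int = 0
    overlap_tolerance_px: int = 0  # allowed overlapping pixels between cells

    def __post_init__(self):
        tp = tuple(float(t) for t in self.time_points)
        if len(tp) == 0 or tp[0] != 0.0:
            raise ValueError("first time point must be 0")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        object.__setattr__(self, "time_points", tp)


@dataclass
class GroundTruth:
    """Ground truth for one simulated field.

    Attributes
    ----------
    label_map : ndarray of int
        Per-pixel cell label (0 = background); identical for every frame.
    cell_table : DataFrame
        One row per (cell, time): true membrane/cytoplasm signal and fraction.
    spot_table : DataFrame
        Spot inventory: label, region, row, col, sigma, weight.
    cells : list of CellSpec
    """

    label_map: np.ndarray
    cell_table: pd.DataFrame
    spot_table: pd.DataFrame
    cells: list[CellSpec]


@dataclass
class ImageSeries:
    """Multi-channel time-lapse for one field.

    ``channels`` maps a role name ("reference", "signal", "marker") to an array
    of shape (T, H, W); ``times_min`` gives the acquisition times in minutes.
    """

    times_min: tuple[float, ...]
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent channel shapes: {shapes}")
        (shape,) = shapes
        if shape[0] != len(self.times_min):
            raise ValueError("channel arrays must have one frame per time point")

    @property
    def frame_shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[1:]

    def frame(self, role: str, t_index: int) -> np.ndarray:
        return self.channels[role][t_index]


# ---------------------------------------------------------------------------
# Layout realization
# ---------------------------------------------------------------------------


@dataclass
class _CellLayout:
    spec: CellSpec
    label: int
    # Fourier radial perturbation (irregular cells): r(theta) = R*(1 + f(theta))
    four_a: np.ndarray  # cos coefficients, harmonics 2..
    four_b: np.ndarray  # sin coefficients
    mem_spots: np.ndarray  # (n, 2) row/col
    cyt_spots: np.ndarray
    mem_weights: np.ndarray  # sum to 1
    cyt_weights: np.ndarray

    def radius_at(self, theta):
        r = np.ones_like(np.asarray(theta, dtype=float))
        for k, (a, b) in enumerate(zip(self.four_a, self.four_b), start=2):
            r = r + a * np.cos(k * theta) + b * np.sin(k * theta)
        return self.spec.radius_px * r


@dataclass
class FieldLayout:
    """Fully realized geometry of a field: outlines, labels and spot positions."""

    cells: list[_CellLayout]
    label_map: np.ndarray
    frame_shape: tuple[int, int]
    reference_factors: np.ndarray  # per-cell staining variability multipliers


def _fourier_coeffs(spec: CellSpec, rng: np.random.Generator, n_harm: int = 4):
    if spec.morphology == "round" or spec.boundary_jitter == 0:
        return np.zeros(n_harm), np.zeros(n_harm)
    a = rng.normal(size=n_harm) / np.arange(2, 2 + n_harm)
    b = rng.normal(size=n_harm) / np.arange(2, 2 + n_harm)
    # scale so the maximum radial perturbation equals boundary_jitter
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    pert = sum(
        a[i] * np.cos((i + 2) * theta) + b[i] * np.sin((i + 2) * theta)
        for i in range(n_harm)
    )
    peak = np.max(np.abs(pert))
    if peak > 0:
        scale = spec.boundary_jitter / peak
        a, b = a * scale, b * scale
    return a, b


def _paint_cell(label_map: np.ndarray, cell: _CellLayout, tol_px: int):
    """Rasterize one cell into the shared label map; count overlap conflicts."""
    (r0, c0) = cell.spec.center
    rmax = cell.spec.radius_px * (1 + cell.spec.boundary_jitter) + 1
    h, w = label_map.shape
    lo_r, hi_r = max(0, int(r0 - rmax)), min(h, int(r0 + rmax) + 1)
    lo_c, hi_c = max(0, int(c0 - rmax)), min(w, int(c0 + rmax) + 1)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dr, dc = rr - r0, cc - c0
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    inside = dist <= cell.radius_at(theta)
    conflict = inside & (label_map[lo_r:hi_r, lo_c:hi_c] != 0)
    n_conflict = int(conflict.sum())
    if n_conflict > tol_px:
        raise FieldOverlapError(
            f"cell {cell.label} at {cell.spec.center} overlaps a previously "
            f"placed cell on {n_conflict} px (tolerance {tol_px})"
        )
    sub = label_map[lo_r:hi_r, lo_c:hi_c]
    sub[inside & (sub == 0)] = cell.label


def _place_spots(cell: _CellLayout, kin: KineticsSpec, rng: np.random.Generator):
    spec = cell.spec
    sigma = kin.spot_sigma_px
    if sigma >= spec.radius_px:
        raise ValueError(
            f"spot sigma {sigma} px exceeds cell radius {spec.radius_px} px"
        )
    r0, c0 = spec.center
    # membrane spots: evenly spaced angles (small jitter) on the true boundary
    n_m = kin.n_spots_membrane
    theta = 2 * np.pi * (np.arange(n_m) + rng.uniform(-0.2, 0.2, n_m)) / max(n_m, 1)
    theta += rng.uniform(0, 2 * np.pi)
    rad = cell.radius_at(theta) + rng.uniform(-0.5, 0.5, n_m)
    cell.mem_spots = np.column_stack([r0 + rad * np.sin(theta), c0 + rad * np.cos(theta)])
    # cytoplasm spots: at least (annulus half-width + 1 + sigma) inside the
    # boundary so their mass stays out of the membrane band, with a minimum
    # mutual separation so they stay resolvable
    margin = MEMBRANE_ANNULUS_HALF_PX + 1.0 + sigma
    n_c = kin.n_spots_cytoplasm
    pts: list[tuple[float, float]] = []
    min_sep = max(3.0, 2.5 * sigma)
    for _ in range(4000):
        if len(pts) == n_c:
            break
        th = rng.uniform(0, 2 * np.pi)
        rmax_th = cell.radius_at(th) - margin
        if rmax_th <= 0.5:
            continue
        rho = rmax_th * np.sqrt(rng.uniform())
        p = (r0 + rho * np.sin(th), c0 + rho * np.cos(th))
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in pts):
            pts.append(p)
    if len(pts) < n_c:
        # cell too small for the requested spot count at this separation;
        # fall back to however many fit (weights renormalize below)
        n_c = max(len(pts), 1) if len(pts) else 0
    cell.cyt_spots = np.asarray(pts[:n_c]).reshape(-1, 2)
    cell.mem_weights = _spot_weights(n_m, rng)
    cell.cyt_weights = _spot_weights(len(cell.cyt_spots), rng)


def _spot_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    w = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    return w / w.sum()


def make_layout(
    cells: Sequence[CellSpec],
    kinetics: KineticsSpec,
    acq: AcquisitionSpec,
) -> FieldLayout:
    """Realize the concrete geometry of a field from its specs (seeded).

    Raises :class:`FieldOverlapError` if cells overlap beyond
    ``acq.overlap_tolerance_px`` and ``ValueError`` if a cell does not fit in
    the frame or the spot width exceeds the cell radius.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(acq.rng_seed), 0xC311]))
    h, w = acq.frame_shape
    label_map = np.zeros((h, w), dtype=np.int32)
    layouts: list[_CellLayout] = []
    for i, spec in enumerate(cells, start=1):
        rmax = spec.radius_px * (1 + spec.boundary_jitter)
        r0, c0 = spec.center
        if not (rmax <= r0 <= h - 1 - rmax and rmax <= c0 <= w - 1 - rmax):
            raise ValueError(f"cell {i} at {spec.center} does not fit within frame")
        a, b = _fourier_coeffs(spec, rng)
        cl = _CellLayout(
            spec=spec, label=i, four_a=a, four_b=b,
            mem_spots=np.zeros((0, 2)), cyt_spots=np.zeros((0, 2)),
            mem_weights=np.zeros(0), cyt_weights=np.zeros(0),
        )
        _paint_cell(label_map, cl, acq.overlap_tolerance_px)
        _place_spots(cl, kinetics, rng)
        layouts.append(cl)
    ref_factors = rng.uniform(0.8, 1.2, size=len(layouts))
    return FieldLayout(
        cells=layouts, label_map=label_map, frame_shape=(h, w),
        reference_factors=ref_factors,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _add_spot(img: np.ndarray, row: float, col: float, sigma: float, mass: float):
    """Add a discretely unit-normalized Gaussian spot carrying ``mass`` AFU."""
    half = int(np.ceil(4 * sigma))
    h, w = img.shape
    lo_r, hi_r = max(0, int(round(row)) - half), min(h, int(round(row)) + half + 1)
    lo_c, hi_c = max(0, int(round(col)) - half), min(w, int(round(col)) + half + 1)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    kern = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))
    s = kern.sum()
    if s > 0:
        img[lo_r:hi_r, lo_c:hi_c] += mass * kern / s


def _render_noiseless(
    layout: FieldLayout, kinetics: KineticsSpec, acq: AcquisitionSpec, t: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    h, w = layout.frame_shape
    ref = np.zeros((h, w), dtype=float)
    sig = np.zeros((h, w), dtype=float)
    marker = np.zeros((h, w), dtype=float)
    frac = float(kinetics.cytoplasm_fraction(t))
    bleach = float(np.exp(-acq.photobleach_rate * t))
    rows = []
    for cl, ref_factor in zip(layout.cells, layout.reference_factors):
        body = layout.label_map == cl.label
        ref[body] += cl.spec.reference_intensity * ref_factor
        if cl.spec.marker_positive:
            marker[body] += 400.0
        total = cl.spec.signal_total * bleach
        mem_total = total * (1.0 - frac)
        cyt_total = total * frac
        sigma = kinetics.spot_sigma_px
        for (r, c), wgt in zip(cl.mem_spots, cl.mem_weights):
            _add_spot(sig, r, c, sigma, mem_total * wgt)
        for (r, c), wgt in zip(cl.cyt_spots, cl.cyt_weights):
            _add_spot(sig, r, c, sigma, cyt_total * wgt)
        rows.append(
            dict(
                label=cl.label, time_min=float(t),
                membrane_signal=mem_total, cytoplasm_signal=cyt_total,
                cytoplasm_fraction=frac, marker_positive=cl.spec.marker_positive,
            )
        )
    return ref, sig, marker, pd.DataFrame(rows)


def _apply_noise(img: np.ndarray, acq: AcquisitionSpec, rng: np.random.Generator):
    img = img + acq.background_level
    if acq.noise_model == "none":
        return img
    if acq.noise_model == "gaussian":
        return img + rng.normal(0.0, acq.gaussian_sigma, size=img.shape)
    # Poisson shot noise on (signal + background), then Gaussian read noise
    noisy = rng.poisson(np.clip(img, 0, None)).astype(float)
    if acq.gaussian_sigma > 0:
        noisy += rng.normal(0.0, acq.gaussian_sigma, size=img.shape)
    return noisy


def render_field(
    cells: Sequence[CellSpec],
    kinetics: KineticsSpec,
    acq: AcquisitionSpec,
    t: float,
    layout: FieldLayout | None = None,
):
    """Render one two-channel frame at time ``t`` (minutes).

    Returns ``(reference, signal, truth)`` where ``truth`` is a
    :class:`GroundTruth` restricted to this single frame.  ``t`` must be one of
    ``acq.time_points``.
    """
    tp = np.asarray(acq.time_points)
    if not np.any(np.isclose(tp, t)):
        raise ValueError(f"t={t} is not in acq.time_points")
    if layout is None:
        layout = make_layout(cells, kinetics, acq)
    t_index = int(np.argmin(np.abs(tp - t)))
    ref, sig, _marker, cell_table = _render_noiseless(layout, kinetics, acq, t)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(acq.rng_seed), 0x11A6E, t_index])
    )
    ref = _apply_noise(ref, acq, rng)
    sig = _apply_noise(sig, acq, rng)
    truth = GroundTruth(
        label_map=layout.label_map.copy(),
        cell_table=cell_table,
        spot_table=_spot_table(layout),
        cells=[cl.spec for cl in layout.cells],
    )
    return ref, sig, truth


def _spot_table(layout: FieldLayout) -> pd.DataFrame:
    rows = []
    for cl in layout.cells:
        for (r, c), wgt in zip(cl.mem_spots, cl.mem_weights):
            rows.append(dict(label=cl.label, region="membrane", row=r, col=c, weight=wgt))
        for (r, c), wgt in zip(cl.cyt_spots, cl.cyt_weights):
            rows.append(dict(label=cl.label, region="cytoplasm", row=r, col=c, weight=wgt))
    return pd.DataFrame(rows, columns=["label", "region", "row", "col", "weight"])


def simulate_series(
    cells: Sequence[CellSpec],
    kinetics: KineticsSpec,
    acq: AcquisitionSpec,
) -> tuple[ImageSeries, GroundTruth]:
    """Simulate the full time-lapse for one field: one frame per time point.

    Bit-for-bit reproducible for a fixed ``acq.rng_seed``.
    """
    layout = make_layout(cells, kinetics, acq)
    has_marker = any(c.marker_positive for c in cells)
    refs, sigs, markers, tables = [], [], [], []
    for t_index, t in enumerate(acq.time_points):
        ref, sig, marker, cell_table = _render_noiseless(layout, kinetics, acq, t)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(acq.rng_seed), 0x11A6E, t_index])
        )
        refs.append(_apply_noise(ref, acq, rng))
        sigs.append(_apply_noise(sig, acq, rng))
        markers.append(_apply_noise(marker, acq, rng))
        tables.append(cell_table)
    channels = {"reference": np.stack(refs), "signal": np.stack(sigs)}
    if has_marker:
        channels["marker"] = np.stack(markers)
    series = ImageSeries(times_min=tuple(acq.time_points), channels=channels)
    truth = GroundTruth(
        label_map=layout.label_map,
        cell_table=pd.concat(tables, ignore_index=True),
        spot_table=_spot_table(layout),
        cells=list(cells),
    )
    return series, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "suspension",
    "adherent",
    "low_expression",
    "overexpression",
    "mixed_population",
)

_LN2 = float(np.log(2.0))


@dataclass
class Preset:
    cells: list[CellSpec]
    kinetics: KineticsSpec
    acq: AcquisitionSpec
    name: str


def _sample_centers(
    n: int, frame_shape, margin: float, min_dist: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    h, w = frame_shape
    pts: list[tuple[float, float]] = []
    for _ in range(200_000):
        if len(pts) == n:
            break
        p = (rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin))
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_dist for q in pts):
            pts.append(p)
    if len(pts) < n:
        raise ValueError(
            f"could not place {n} non-overlapping cells in a {h}x{w} frame"
        )
    return pts


def make_preset(
    name: str,
    *,
    seed: int = 0,
    n_cells: int | None = None,
    t_half_min: float | None = None,
    time_points: Iterable[float] | None = None,
    positive_fraction: float = 0.05,
    noise_model: str = "poisson",
) -> Preset:
    """Build the (cells, kinetics, acq) bundle for a named experimental system.

    Presets
    -------
    suspension
        Round cells, default-expression signal; emulates a suspension line
        (e.g. an erythroleukemic line) imaged over 3 h.
    adherent
        Irregular, size-heterogeneous outlines; same kinetic protocol.
    low_expression
        Round cells with total signal scaled to the ~5,000 receptors/cell
        regime (1/10 of the default 50,000-AFU scale), fewer brighter
        clusters, slower default kinetics, 8 time points over 6 h.
    overexpression
        Round cells with 10x the default signal, fast kinetics, dense early
        sampling.
    mixed_population
        Many small cells of which only a ``positive_fraction`` minority is
        marker-positive and carries drug signal (whole-blood-like field);
        adds a marker channel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBEE5]))
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    frame = (512, 512)
    if name == "suspension":
        n = 60 if n_cells is None else n_cells
        th = 34.0 if t_half_min is None else t_half_min
        tp = (0, 30, 60, 90, 120, 150, 180) if time_points is None else tuple(time_points)
        radii = np.clip(rng.normal(14.0, 0.8, n), 12.5, 15.5)
        centers = _sample_centers(n, frame, margin=22, min_dist=33, rng=rng)
        cells = [
            CellSpec(center=c, radius_px=float(r)) for c, r in zip(centers, radii)
        ]
        kin = KineticsSpec(k_int_true=_LN2 / th)
    elif name == "adherent":
        n = 50 if n_cells is None else n_cells
        th = 23.0 if t_half_min is None else t_half_min
        tp = (0, 30, 60, 90, 120, 150, 180) if time_points is None else tuple(time_points)
        radii = rng.uniform(12.0, 16.0, n)
        centers = _sample_centers(n, frame, margin=24, min_dist=38, rng=rng)
        cells = [
            CellSpec(
                center=c, radius_px=float(r), morphology="irregular",
                boundary_jitter=0.2,
            )
            for c, r in zip(centers, radii)
        ]
        kin = KineticsSpec(k_int_true=_LN2 / th)
    elif name == "low_expression":
        n = 60 if n_cells is None else n_cells
        th = 110.0 if t_half_min is None else t_half_min
        tp = (
            (0, 45, 90, 135, 180, 240, 300, 360)
            if time_points is None
            else tuple(time_points)
        )
        radii = np.clip(rng.normal(14.0, 0.8, n), 12.5, 15.5)
        centers = _sample_centers(n, frame, margin=22, min_dist=33, rng=rng)
        cells = [
            CellSpec(center=c, radius_px=float(r), signal_total=5_000.0)
            for c, r in zip(centers, radii)
        ]
        kin = KineticsSpec(
            k_int_true=_LN2 / th, n_spots_membrane=5, n_spots_cytoplasm=4,
            spot_sigma_px=1.0,
        )
    elif name == "overexpression":
        n = 60 if n_cells is None else n_cells
        th = 8.0 if t_half_min is None else t_half_min
        tp = (0, 5, 10, 15, 20, 30, 45, 60) if time_points is None else tuple(time_points)
        radii = np.clip(rng.normal(14.0, 0.8, n), 12.5, 15.5)
        centers = _sample_centers(n, frame, margin=22, min_dist=33, rng=rng)
        cells = [
            CellSpec(center=c, radius_px=float(r), signal_total=500_000.0)
            for c, r in zip(centers, radii)
        ]
        kin = KineticsSpec(k_int_true=_LN2 / th)
    else:  # mixed_population
        n = 200 if n_cells is None else n_cells
        th = 34.0 if t_half_min is None else t_half_min
        tp = (0, 30, 60, 90, 120, 150, 180) if time_points is None else tuple(time_points)
        frame = (640, 640)
        n_pos = int(round(positive_fraction * n))
        positive = np.zeros(n, dtype=bool)
        positive[:n_pos] = True  # deterministic count; placement is random
        radii = np.clip(rng.normal(9.0, 0.6, n), 7.5, 10.5)
        centers = _sample_centers(n, frame, margin=16, min_dist=23, rng=rng)
        cells = [
            CellSpec(
                center=c, radius_px=float(r),
                signal_total=50_000.0 if pos else 0.0, marker_positive=bool(pos),
            )
            for c, r, pos in zip(centers, radii, positive)
        ]
        kin = KineticsSpec(k_int_true=_LN2 / th)
    acq = AcquisitionSpec(
        frame_shape=frame, time_points=tp, noise_model=noise_model, rng_seed=int(seed)
    )
    return Preset(cells=cells, kinetics=kin, acq=acq, name=name)


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

CHANNEL_INDEX = {"reference": 1, "signal": 2, "marker": 3}


def write_series(
    series: ImageSeries,
    truth: GroundTruth | None,
    outdir: str | Path,
    plate: str = "plate1",
    well: str = "A01",
    field: str = "f01",
    params: dict | None = None,
) -> Path:
    """Write a simulated field to disk in the pipeline's on-disk layout.

    One TIFF per frame per channel named ``t{index:02d}_c{channel}.tif`` under
    ``{plate}/{well}/{field}/``, a 16-bit label-map TIFF and a spot-inventory
    CSV for the ground truth, plus a YAML sidecar echoing times and parameters.
    """
    base = Path(outdir) / plate / well / field
    base.mkdir(parents=True, exist_ok=True)
    for role, arr in series.channels.items():
        ci = CHANNEL_INDEX[role]
        for ti in range(arr.shape[0]):
            tifffile.imwrite(
                base / f"t{ti:02d}_c{ci}.tif",
                np.clip(arr[ti], 0, 65535).astype(np.uint16),
            )
    if truth is not None:
        tifffile.imwrite(
            base / "labels.tif", truth.label_map.astype(np.uint16)
        )
        truth.spot_table.to_csv(base / "spots_truth.csv", index=False)
        truth.cell_table.to_csv(base / "cells_truth.csv", index=False)
    sidecar = {
        "times_min": [float(t) for t in series.times_min],
        "channels": {role: CHANNEL_INDEX[role] for role in series.channels},
    }
    if params:
        sidecar["params"] = params
    (base / "generation.yaml").write_text(yaml.safe_dump(sidecar))
    return base
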