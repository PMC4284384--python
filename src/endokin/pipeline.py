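"""Run configuration, image I/O and end-to-end orchestration.

Turns the algorithm stages into a runnable pipeline over a plate layout on
disk: TIFF frames organized as ``{plate}/{well}/{field}/t{index}_c{channel}.tif``
are segmented (reference channel at t = 0; regions reused across the time
course since cells are static), spot-quantified per frame, normalized and fit
per replicate group.  Every output row carries the configuration hash so
results are traceable; failures are contained per well.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .kinetics import InternalizationModel, InternalizationResults, normalize
from .segmentation import SegmentationParams, segment_frame
from .spots import SpotParams, quantify_frame, spots_to_frame
from .synthetic import ImageSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ProvenanceLog",
    "PipelineResult",
    "read_series",
    "run_pipeline",
    "quantify_series",
]

_FRAME_RE = re.compile(r"^t(\d+)_c(\d+)\.tif$")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``channel_roles`` maps role names to on-disk channel indices; ``wells``
    maps well ids to replicate-group names (wells in the same group are fitted
    together as replicates).  ``times_min`` are minutes since internalization
    start for each frame index — timestamps come from configuration, not file
    mtimes, for reproducibility.
    """

    input_dir: str
    output_dir: str
    plate: str = "plate1"
    wells: dict[str, str] = field(default_factory=dict)  # well -> replicate group
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"reference": 1, "signal": 2}
    )
    times_min: list[float] = field(default_factory=list)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spots: SpotParams = field(default_factory=SpotParams)
    pooled_fit: bool = False
    resegment_each_frame: bool = False
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        roles = list(self.channel_roles.values())
        if len(set(roles)) != len(roles):
            raise ValueError("channel roles must map to distinct channel indices")
        if "reference" not in self.channel_roles or "signal" not in self.channel_roles:
            raise ValueError("channel_roles must include 'reference' and 'signal'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("segmentation", "spots"):
            if key in raw and isinstance(raw[key], dict):
                params_cls = SegmentationParams if key == "segmentation" else SpotParams
                val = dict(raw[key])
                if "marker_gate" in val and isinstance(val["marker_gate"], list):
                    val["marker_gate"] = tuple(val["marker_gate"])
                if "bg_annulus_px" in val and isinstance(val["bg_annulus_px"], list):
                    val["bg_annulus_px"] = tuple(val["bg_annulus_px"])
                raw[key] = params_cls(**val)
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (excludes output destination and
        logging, which do not affect results)."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj
        payload = enc(self)
        payload.pop("output_dir", None)
        payload.pop("log_level", None)
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class ProvenanceLog:
    """Run metadata: config hash, software version, parameter echo, warnings."""

    config_hash: str
    version: str
    parameters: dict
    warnings: list[str] = field(default_factory=list)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            dict(config_hash=self.config_hash, version=self.version,
                 parameters=self.parameters, warnings=self.warnings),
            sort_keys=False,
        )


@dataclass
class PipelineResult:
    region_signals: pd.DataFrame
    fits: dict[str, InternalizationResults]  # replicate group -> results
    spot_tables: dict[tuple[str, int], pd.DataFrame]  # (well, t_index) -> spots
    provenance: ProvenanceLog
    failed_wells: dict[str, str] = field(default_factory=dict)


def read_series(
    field_dir: str | Path, channel_roles: dict[str, int], times_min: list[float]
) -> ImageSeries:
    """Read one field's TIFF frames into an ordered multi-channel series.

    Missing time points are reported with a warning; inconsistent frame shapes
    raise an error naming the offending file.
    """
    field_dir = Path(field_dir)
    files: dict[tuple[int, int], Path] = {}
    for p in sorted(field_dir.iterdir()):
        m = _FRAME_RE.match(p.name)
        if m:
            files[(int(m.group(1)), int(m.group(2)))] = p
    if not files:
        raise FileNotFoundError(f"no frames matching t*_c*.tif under {field_dir}")
    t_indices = sorted({t for t, _ in files})
    expected = list(range(len(times_min)))
    missing = [i for i in expected if i not in t_indices]
    if missing:
        warnings.warn(
            f"{field_dir}: missing time indices {missing}; proceeding with gaps",
            stacklevel=2,
        )
    t_indices = [i for i in expected if i in t_indices]
    channels: dict[str, list[np.ndarray]] = {role: [] for role in channel_roles}
    shape = None
    for ti in t_indices:
        for role, ci in channel_roles.items():
            p = files.get((ti, ci))
            if p is None:
                raise FileNotFoundError(
                    f"frame t{ti:02d}_c{ci}.tif absent under {field_dir}"
                )
            arr = tifffile.imread(p).astype(float)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(f"inconsistent frame shape in {p}: {arr.shape} != {shape}")
            channels[role].append(arr)
    times = tuple(times_min[i] for i in t_indices)
    return ImageSeries(
        times_min=times, channels={r: np.stack(v) for r, v in channels.items()}
    )


def quantify_series(
    series: ImageSeries,
    seg_params: SegmentationParams,
    spot_params: SpotParams,
    well: str = "",
    resegment_each_frame: bool = False,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Segment (t = 0 unless resegmenting) and quantify every frame of a field.

    Returns the per-time region-signal table and per-frame spot tables.
    """
    marker = series.channels.get("marker")
    cells, regions = segment_frame(
        series.frame("reference", 0), seg_params,
        marker_frame=None if marker is None else marker[0],
    )
    rows, spot_tables = [], {}
    for ti, t in enumerate(series.times_min):
        if resegment_each_frame and ti > 0:
            cells, regions = segment_frame(
                series.frame("reference", ti), seg_params,
                marker_frame=None if marker is None else marker[ti],
            )
        sig, spots = quantify_frame(
            series.frame("signal", ti), regions, spot_params, well=well, time_min=t
        )
        rows.append(dataclasses.asdict(sig))
        spot_tables[ti] = spots_to_frame(spots)
    return pd.DataFrame(rows), spot_tables


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute segmentation -> spot quantification -> kinetics over a plate.

    Wells are processed independently; a failure in one well is recorded and
    does not abort the others.  All tables and the provenance log are written
    under ``config.output_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    chash = config.config_hash()
    prov = ProvenanceLog(
        config_hash=chash, version=__version__,
        parameters=dataclasses.asdict(config),
    )
    in_dir = Path(config.input_dir) / config.plate
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_signals: list[pd.DataFrame] = []
    spot_tables: dict[tuple[str, int], pd.DataFrame] = {}
    failed: dict[str, str] = {}
    for well in sorted(config.wells):
        well_dir = in_dir / well
        try:
            if not well_dir.is_dir():
                raise FileNotFoundError(f"well directory missing: {well_dir}")
            field_frames = []
            for field_dir in sorted(d for d in well_dir.iterdir() if d.is_dir()):
                series = read_series(field_dir, config.channel_roles, config.times_min)
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    sig_df, spots = quantify_series(
                        series, config.segmentation, config.spots, well=well,
                        resegment_each_frame=config.resegment_each_frame,
                    )
                prov.warnings.extend(f"{well}/{field_dir.name}: {w.message}" for w in caught)
                sig_df.insert(0, "field", field_dir.name)
                field_frames.append(sig_df)
                for ti, tbl in spots.items():
                    spot_tables[(well, ti)] = tbl
            if not field_frames:
                raise FileNotFoundError(f"no field directories under {well_dir}")
            well_df = pd.concat(field_frames, ignore_index=True)
            # pool fields: sum intensities and areas before dividing
            pooled = _pool_fields(well_df, well)
            all_signals.append(pooled)
        except Exception as exc:  # noqa: BLE001 - per-well containment
            logger.error("well %s failed: %s", well, exc)
            failed[well] = str(exc)
    if not all_signals:
        raise RuntimeError(f"every well failed: {failed}")
    signals = pd.concat(all_signals, ignore_index=True)
    signals["plate"] = config.plate
    signals["config_hash"] = chash

    fits: dict[str, InternalizationResults] = {}
    groups: dict[str, list[str]] = {}
    for well, grp in config.wells.items():
        groups.setdefault(grp, []).append(well)
    for grp, wells in sorted(groups.items()):
        sub = signals[signals["well"].isin(wells)]
        if sub.empty:
            failed[f"group:{grp}"] = "no successful wells"
            continue
        try:
            res = InternalizationModel.from_dataframe(sub, pooled=config.pooled_fit).fit()
            fits[grp] = res
        except Exception as exc:  # noqa: BLE001
            failed[f"group:{grp}"] = str(exc)

    _write_outputs(out_dir, chash, signals, fits, spot_tables, prov)
    return PipelineResult(
        region_signals=signals, fits=fits, spot_tables=spot_tables,
        provenance=prov, failed_wells=failed,
    )


def _pool_fields(well_df: pd.DataFrame, well: str) -> pd.DataFrame:
    rows = []
    for t, grp in well_df.groupby("time_min", sort=True):
        mem_area = grp["membrane_area_px"].sum()
        cyt_area = grp["cytoplasm_area_px"].sum()
        rows.append(
            dict(
                well=well, time_min=float(t),
                membrane_signal=(grp["membrane_signal"] * grp["membrane_area_px"]).sum() / mem_area,
                cytoplasm_signal=(grp["cytoplasm_signal"] * grp["cytoplasm_area_px"]).sum() / cyt_area,
                n_cells=int(grp["n_cells"].sum()),
                n_spots_membrane=int(grp["n_spots_membrane"].sum()),
                n_spots_cytoplasm=int(grp["n_spots_cytoplasm"].sum()),
                membrane_area_px=int(mem_area),
                cytoplasm_area_px=int(cyt_area),
            )
        )
    return pd.DataFrame(rows)


def _write_outputs(out_dir, chash, signals, fits, spot_tables, prov):
    signals.to_csv(out_dir / "region_signals.csv", index=False)
    fit_rows = []
    for grp, res in sorted(fits.items()):
        df = res.to_frame()
        df.insert(0, "group", grp)
        df["config_hash"] = chash
        fit_rows.append(df)
    if fit_rows:
        pd.concat(fit_rows, ignore_index=True).to_csv(out_dir / "fits.csv", index=False)
    spot_dir = out_dir / "spots"
    spot_dir.mkdir(exist_ok=True)
    for (well, ti), tbl in sorted(spot_tables.items()):
        out = tbl.copy()
        out["config_hash"] = chash
        out.to_csv(spot_dir / f"{well}_t{ti:02d}.csv", index=False)
    (out_dir / "provenance.yaml").write_text(prov.to_yaml())
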