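"""Internalization kinetics: normalization, exponential fitting, half-life.

The cytoplasm signal of each replicate well is normalized by the total cell
signal at each time point,

    f(t) = S_cyt / (S_cyt + S_mem),

which cancels staining variability and common-mode photobleaching, and the
rate constant is obtained by nonlinear least squares of the mono-exponential
association model

    S_cyt(t) = S_0,cyt + (1 - exp(-k_int * t)) * S_max,cyt,

with the internalization half-life T1/2 = ln2 / k_int.  The fit is exposed as
a statsmodels-style pair: :class:`InternalizationModel` (data + options) whose
``fit()`` returns :class:`InternalizationResults` (per-replicate estimates,
across-replicate mean +/- SD, diagnostics, ``summary()``).

Also provides the acid-dissociation end-point calculator used to corroborate
imaging-derived internalization: surface fraction = 1 - FL_acid/FL_PBS per
condition, and internalized percent = the loss of surface signal at 37 C
relative to the 4 C (no-internalization) reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .spots import RegionSignal

__all__ = [
    "NormalizedSeries",
    "ReplicateFit",
    "InternalizationModel",
    "InternalizationResults",
    "AcidDissociationRecord",
    "normalize",
    "fit_internalization",
    "half_life",
    "acid_dissociation",
]

_LN2 = float(np.log(2.0))

# deterministic multi-start grid for k_int (1/min): spans half-lives 5..240 min
_KGRID_THALF = (5.0, 15.0, 30.0, 60.0, 120.0, 240.0)
# below this fitted amplitude a series is declared flat (no internalization)
_FLAT_SMAX = 0.02


@dataclass
class NormalizedSeries:
    """Normalized cytoplasm-fraction time courses, one column per replicate."""

    times_min: np.ndarray
    fractions: pd.DataFrame  # index: time, columns: replicate ids
    dropped_times: list[float] = field(default_factory=list)

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        self.times_min = t


def normalize(signals: list[RegionSignal] | pd.DataFrame) -> NormalizedSeries:
    """Convert per-well region signals into normalized cytoplasm fractions.

    Accepts a list of :class:`~endokin.spots.RegionSignal` or a DataFrame with
    columns (well, time_min, membrane_signal, cytoplasm_signal).  Time points
    where membrane + cytoplasm signal is zero in some well are dropped (with a
    warning); an error is raised if nothing survives.
    """
    if isinstance(signals, pd.DataFrame):
        df = signals.copy()
    else:
        df = pd.DataFrame(
            dict(
                well=s.well, time_min=s.time_min,
                membrane_signal=s.membrane_signal,
                cytoplasm_signal=s.cytoplasm_signal,
            )
            for s in signals
        )
    df["total"] = df["membrane_signal"] + df["cytoplasm_signal"]
    bad = df.loc[df["total"] <= 0, "time_min"].unique().tolist()
    if bad:
        warnings.warn(f"dropping time points with zero total signal: {bad}", stacklevel=2)
        df = df[~df["time_min"].isin(bad)]
    if df.empty:
        raise ValueError("all time points had zero total signal")
    df["fraction"] = df["cytoplasm_signal"] / df["total"]
    wide = df.pivot_table(index="time_min", columns="well", values="fraction").sort_index()
    return NormalizedSeries(
        times_min=wide.index.to_numpy(dtype=float),
        fractions=wide,
        dropped_times=[float(b) for b in bad],
    )


def _exp_model(t, s0, smax, k):
    return s0 + (1.0 - np.exp(-k * t)) * smax


@dataclass
class ReplicateFit:
    """Fit of one replicate well."""

    replicate: str
    k_int: float  # 1/min
    s0_cyt: float
    smax_cyt: float
    t_half_min: float
    rss: float
    converged: bool
    flat: bool  # True when no internalization was detected (smax ~ 0)


def _fit_one(t: np.ndarray, y: np.ndarray) -> ReplicateFit:
    """Constrained least squares with deterministic multi-start.

    Parameterized as s0 = a, smax = (1 - a) * b with a, b in [0, 1] so the
    physical constraint s0 + smax <= 1 holds exactly; k is fit in log space.
    """
    mask = np.isfinite(y)
    t, y = t[mask], y[mask]

    def resid(p):
        a, b, logk = p
        return _exp_model(t, a, (1 - a) * b, np.exp(logk)) - y

    best = None
    a0 = float(np.clip(y[0], 0.0, 1.0))
    span = float(np.clip(y[-1] - y[0], 0.0, 1.0))
    b0 = float(np.clip(span / max(1 - a0, 1e-6), 0.05, 0.95))
    for th in _KGRID_THALF:
        try:
            sol = least_squares(
                resid,
                x0=[np.clip(a0, 1e-6, 1 - 1e-6), b0, np.log(_LN2 / th)],
                bounds=([0.0, 0.0, np.log(1e-6)], [1.0, 1.0, np.log(10.0)]),
                method="trf",
            )
        except Exception:  # pragma: no cover - solver pathologies
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return ReplicateFit("", np.nan, np.nan, np.nan, np.nan, np.inf, False, False)
    a, b, logk = best.x
    s0 = float(a)
    smax = float((1 - a) * b)
    k = float(np.exp(logk))
    rss = float(2 * best.cost)
    if smax < _FLAT_SMAX:
        return ReplicateFit("", np.nan, s0, smax, np.nan, rss, True, True)
    return ReplicateFit("", k, s0, smax, _LN2 / k, rss, True, False)


class InternalizationModel:
    """Mono-exponential internalization model for normalized time courses.

    Parameters
    ----------
    series : NormalizedSeries
        Normalized cytoplasm fractions per replicate well (>= 4 time points).
    pooled : bool
        Fit all replicates jointly as one data set instead of per well.
    """

    def __init__(self, series: NormalizedSeries, pooled: bool = False):
        if len(series.times_min) < 4:
            raise ValueError("need >= 4 distinct time points to fit")
        if not np.all(np.isfinite(series.fractions.to_numpy()[np.isfinite(series.fractions.to_numpy())])):
            raise ValueError("fractions must be finite")
        self.series = series
        self.pooled = pooled

    @classmethod
    def from_signals(cls, signals, **kw) -> "InternalizationModel":
        return cls(normalize(signals), **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "InternalizationModel":
        return cls(normalize(df), **kw)

    def fit(self) -> "InternalizationResults":
        t = self.series.times_min
        fits: list[ReplicateFit] = []
        if self.pooled:
            cols = list(self.series.fractions.columns)
            tt = np.tile(t, len(cols))
            yy = self.series.fractions.to_numpy().T.ravel()
            f = _fit_one(tt, yy)
            f.replicate = "pooled"
            fits.append(f)
        else:
            for col in self.series.fractions.columns:
                f = _fit_one(t, self.series.fractions[col].to_numpy(dtype=float))
                f.replicate = str(col)
                fits.append(f)
        return InternalizationResults(self, fits)


class InternalizationResults:
    """Results of :meth:`InternalizationModel.fit`.

    Per-replicate parameter estimates plus the across-replicate mean +/- SD of
    the half-life — the spread reported is the standard deviation over
    replicate wells, not a fit standard error.
    """

    def __init__(self, model: InternalizationModel, fits: list[ReplicateFit]):
        self.model = model
        self.replicate_fits = fits

    @property
    def converged(self) -> bool:
        return any(f.converged and not f.flat for f in self.replicate_fits)

    @property
    def no_internalization(self) -> bool:
        return all(f.flat for f in self.replicate_fits if f.converged)

    def _good(self) -> list[ReplicateFit]:
        return [f for f in self.replicate_fits if f.converged and not f.flat]

    @property
    def k_int(self) -> float:
        """Mean k_int (1/min) over converged, non-flat replicates."""
        good = self._good()
        if not good:
            raise ValueError("no internalization detected; k_int not reported")
        return float(np.mean([f.k_int for f in good]))

    @property
    def t_half(self) -> float:
        """Mean internalization half-life (min) over replicates."""
        good = self._good()
        if not good:
            raise ValueError("no internalization detected; T1/2 not reported")
        return float(np.mean([f.t_half_min for f in good]))

    @property
    def t_half_sd(self) -> float:
        good = self._good()
        if len(good) < 2:
            return float("nan")
        return float(np.std([f.t_half_min for f in good], ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                replicate=f.replicate, k_int_per_min=f.k_int, s0_cyt=f.s0_cyt,
                smax_cyt=f.smax_cyt, t_half_min=f.t_half_min, rss=f.rss,
                converged=f.converged, flat=f.flat,
            )
            for f in self.replicate_fits
        )

    def summary(self) -> str:
        lines = [
            "Internalization kinetics fit",
            "  model: S_cyt(t) = S0 + (1 - exp(-k_int t)) Smax   [normalized fraction]",
            f"  replicates: {len(self.replicate_fits)}"
            + ("  (pooled)" if self.model.pooled else ""),
            "",
            f"  {'replicate':>12} {'k_int/min':>11} {'S0':>7} {'Smax':>7} "
            f"{'T1/2 min':>9} {'RSS':>10} {'flag':>6}",
        ]
        for f in self.replicate_fits:
            flag = "flat" if f.flat else ("ok" if f.converged else "fail")
            lines.append(
                f"  {f.replicate:>12} {f.k_int:>11.5f} {f.s0_cyt:>7.3f} "
                f"{f.smax_cyt:>7.3f} {f.t_half_min:>9.2f} {f.rss:>10.3e} {flag:>6}"
            )
        if self._good():
            sd = self.t_half_sd
            sd_txt = f" +/- {sd:.1f}" if np.isfinite(sd) else ""
            lines += ["", f"  T1/2 = {self.t_half:.1f}{sd_txt} min (mean +/- SD across wells)"]
        else:
            lines += ["", "  no internalization detected"]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the normalized time courses with their fitted curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.series.times_min
        t_fine = np.linspace(t[0], t[-1], 200)
        for col, f in zip(self.series.fractions.columns, self.replicate_fits):
            pts = ax.plot(t, self.series.fractions[col], "o", label=str(col))
            if f.converged and not f.flat:
                ax.plot(t_fine, _exp_model(t_fine, f.s0_cyt, f.smax_cyt, f.k_int),
                        "-", color=pts[0].get_color())
        ax.set_xlabel("time (min)")
        ax.set_ylabel("normalized cytoplasm signal")
        ax.set_ylim(0, 1)
        ax.legend(title="replicate", fontsize="small")
        return ax

    @property
    def series(self) -> NormalizedSeries:
        return self.model.series


def fit_internalization(
    series: NormalizedSeries, pooled: bool = False
) -> InternalizationResults:
    """Functional wrapper around :class:`InternalizationModel`."""
    return InternalizationModel(series, pooled=pooled).fit()


def half_life(k_int: float) -> float:
    """Internalization half-life (min) = ln2 / k_int; k_int must be > 0."""
    if k_int <= 0:
        raise ValueError("k_int must be > 0")
    return _LN2 / k_int


@dataclass
class AcidDissociationRecord:
    """Acid-dissociation end-point assay: surface vs internalized fractions."""

    fl_pbs_4c: float
    fl_acid_4c: float
    fl_pbs_37c: float
    fl_acid_37c: float
    surface_frac_4c: float = float("nan")
    surface_frac_37c: float = float("nan")
    internalized_percent: float = float("nan")
    anomalous: bool = False


def acid_dissociation(
    fl_pbs_4c: float, fl_acid_4c: float, fl_pbs_37c: float, fl_acid_37c: float
) -> AcidDissociationRecord:
    """Compute internalized percent from four median-fluorescence readings.

    Surface fraction per condition is 1 - FL_acid/FL_PBS (the share of signal
    strippable by acid); internalized percent is the decrease in surface
    fraction at 37 C relative to the 4 C reference:

        100 * (surface_4C - surface_37C) / surface_4C.
    """
    for name, v in (
        ("fl_pbs_4c", fl_pbs_4c), ("fl_acid_4c", fl_acid_4c),
        ("fl_pbs_37c", fl_pbs_37c), ("fl_acid_37c", fl_acid_37c),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be > 0")
    surf_4 = 1.0 - fl_acid_4c / fl_pbs_4c
    surf_37 = 1.0 - fl_acid_37c / fl_pbs_37c
    if surf_4 <= 0:
        raise ValueError("surface fraction at 4 C is <= 0: invalid reference")
    pct = 100.0 * (surf_4 - surf_37) / surf_4
    anomalous = pct < 0
    if anomalous:
        warnings.warn("negative internalized percent: assay anomaly", stacklevel=2)
    return AcidDissociationRecord(
        fl_pbs_4c=fl_pbs_4c, fl_acid_4c=fl_acid_4c,
        fl_pbs_37c=fl_pbs_37c, fl_acid_37c=fl_acid_37c,
        surface_frac_4c=surf_4, surface_frac_37c=surf_37,
        internalized_percent=pct, anomalous=anomalous,
    )
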