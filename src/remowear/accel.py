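"""Raw wrist-accelerometer ingest, calibration, and 1-s epoch summaries.

The sensor reports integer counts on three axes at a nominal 10 Hz with a
±8 g range and 4,096 counts per g.  Processing converts counts to g,
estimates a fixed vector-magnitude bias from quiet-stationary intervals,
and reduces the stream to per-second epoch statistics that every
downstream stage (non-wear detection, step counting, the Activity Index)
consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import runs_of_true

COUNTS_PER_G = 4096
COUNT_LIMIT = 32768  # ±8 g at 4,096 counts/g
DEFAULT_SAMPLE_RATE = 10.0
DEFAULT_ANCHOR = datetime(2000, 1, 1, 0, 0, 0)

#: Default quiet-stationary movement threshold: 13 mg vector-magnitude SD.
STATIONARY_SD_G = 0.013
STATIONARY_WINDOW_S = 10
STATIONARY_MIN_S = 60.0


class SchemaError(ValueError):
    """Raw CSV is missing a required column."""


class RawParseError(ValueError):
    """Raw CSV contains a non-numeric payload; message carries the line number."""


class EmptyInputError(ValueError):
    """Raw CSV contains no data rows."""


class RangeError(ValueError):
    """A count falls outside the sensor's ±32,768 range."""


class CalibrationError(ValueError):
    """Not enough quiet-stationary data to estimate calibration."""


@dataclass
class RawSampleSeries:
    """Timestamped triaxial integer-count samples from the wrist sensor.

    ``t`` holds seconds relative to ``anchor`` (a local-clock datetime);
    timestamps are strictly increasing after duplicate removal.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    device_id: str = ""
    anchor: datetime = field(default_factory=lambda: DEFAULT_ANCHOR)

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("axis arrays must share one length")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AccelSeries:
    """Triaxial acceleration in g, sharing the raw series' time base."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    device_id: str = ""
    anchor: datetime = field(default_factory=lambda: DEFAULT_ANCHOR)

    @property
    def vm(self) -> np.ndarray:
        """Vector magnitude sqrt(x² + y² + z²), in g."""
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class CalibrationParams:
    """Fixed calibration derived from quiet-stationary wear.

    bias
        Scalar offset of the stationary vector magnitude from 1 g.
    noise_floor
        g; corrected VM deviations smaller than this are clamped to zero.
    sigma_bar_sq
        Systematic per-axis noise variance σ̄² (g²), the reference
        variance of the Activity Index.
    """

    bias: float = 0.0
    noise_floor: float = STATIONARY_SD_G
    sigma_bar_sq: float = STATIONARY_SD_G**2

    def __post_init__(self) -> None:
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        if self.sigma_bar_sq <= 0:
            raise ValueError("sigma_bar_sq must be > 0")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"bias": self.bias, "noise_floor": self.noise_floor, "sigma_bar_sq": self.sigma_bar_sq}
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(bias=d["bias"], noise_floor=d["noise_floor"], sigma_bar_sq=d["sigma_bar_sq"])


#: Fallback used when a recording contains no usable stationary interval.
DEFAULT_CALIBRATION = CalibrationParams()


@dataclass
class EpochSeries:
    """Per-second summaries of a calibrated acceleration stream.

    One record per elapsed second from the first sample.  Epochs with no
    samples are retained with ``n_samples == 0`` and NaN statistics —
    gaps are never silently dropped.  ``vm_bc`` is the bias-corrected
    vector-magnitude deviation from 1 g with sub-noise-floor values
    clamped to zero, so it is always >= 0.
    """

    epoch_start: np.ndarray  # seconds since anchor, integer-second aligned
    mean_x: np.ndarray
    mean_y: np.ndarray
    mean_z: np.ndarray
    sd_x: np.ndarray
    sd_y: np.ndarray
    sd_z: np.ndarray
    vm_mean: np.ndarray
    vm_sd: np.ndarray
    vm_bc: np.ndarray
    n_samples: np.ndarray
    anchor: datetime = field(default_factory=lambda: DEFAULT_ANCHOR)

    def __len__(self) -> int:
        return len(self.epoch_start)

    def local_datetimes(self) -> np.ndarray:
        """Local-clock datetime of each epoch start."""
        return np.array([self.anchor + timedelta(seconds=float(s)) for s in self.epoch_start])

    def local_hours(self) -> np.ndarray:
        """Local-clock hour-of-day (0–23) of each epoch."""
        base = self.anchor.hour * 3600 + self.anchor.minute * 60 + self.anchor.second
        return ((base + self.epoch_start.astype(np.int64)) % 86400) // 3600

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_start": self.epoch_start,
                "mean_x": self.mean_x,
                "mean_y": self.mean_y,
                "mean_z": self.mean_z,
                "sd_x": self.sd_x,
                "sd_y": self.sd_y,
                "sd_z": self.sd_z,
                "vm_mean": self.vm_mean,
                "vm_sd": self.vm_sd,
                "vm_bc": self.vm_bc,
                "n_samples": self.n_samples,
            }
        )


def read_raw(path: str | Path, dialect: dict | None = None) -> RawSampleSeries:
    """Read a raw accelerometer CSV (``time,x,y,z``; gzip accepted).

    ``time`` may be ISO-8601 local timestamps (the first becomes the
    series anchor) or float seconds since an anchor supplied via
    ``dialect={"anchor": datetime}``.  Rows are sorted by time and
    duplicate timestamps collapsed keeping the first occurrence; gaps
    are preserved, never interpolated.
    """
    dialect = dict(dialect or {})
    anchor = dialect.pop("anchor", None)
    device_id = dialect.pop("device_id", "")
    sample_rate = dialect.pop("sample_rate", DEFAULT_SAMPLE_RATE)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, **dialect)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    for col in ("time", "x", "y", "z"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    counts = {}
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2  # +1 header, +1 one-based

            raise RawParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        counts[col] = vals.to_numpy()

    time_col = df["time"]
    t_num = pd.to_numeric(time_col, errors="coerce")
    if not t_num.isna().any():
        t = t_num.to_numpy(dtype=float)
        if anchor is None:
            anchor = DEFAULT_ANCHOR
    else:
        ts = pd.to_datetime(time_col, errors="coerce", format="ISO8601")
        if ts.isna().any():
            line = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 2
            raise RawParseError(f"{path}: unparseable time at line {line}")
        anchor = ts.iloc[0].to_pydatetime() if anchor is None else anchor
        t = (ts - pd.Timestamp(anchor)).dt.total_seconds().to_numpy()

    order = np.argsort(t, kind="stable")
    t = t[order]
    xyz = {c: counts[c][order] for c in ("x", "y", "z")}
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = np.diff(t) > 0  # drop exact duplicates, keep first
    return RawSampleSeries(
        t=t[keep],
        x=xyz["x"][keep].astype(np.int64),
        y=xyz["y"][keep].astype(np.int64),
        z=xyz["z"][keep].astype(np.int64),
        sample_rate=float(sample_rate),
        device_id=str(device_id),
        anchor=anchor,
    )


def counts_to_g(raw: RawSampleSeries) -> AccelSeries:
    """Convert integer counts to g: value_g = count / 4096 per axis."""
    for name, arr in (("x", raw.x), ("y", raw.y), ("z", raw.z)):
        bad = np.abs(arr) > COUNT_LIMIT
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise RangeError(
                f"count {int(arr[i])} on axis {name} at index {i} outside ±{COUNT_LIMIT}"
            )
    return AccelSeries(
        t=np.asarray(raw.t, dtype=float),
        x=raw.x / COUNTS_PER_G,
        y=raw.y / COUNTS_PER_G,
        z=raw.z / COUNTS_PER_G,
        sample_rate=raw.sample_rate,
        device_id=raw.device_id,
        anchor=raw.anchor,
    )


def _second_bins(t: np.ndarray) -> tuple[np.ndarray, int]:
    """Bin sample times into integer seconds from the first sample."""
    t0 = t[0]
    sec = np.floor(t - t0).astype(np.int64)
    n_sec = int(sec[-1]) + 1
    return sec, n_sec


def find_stationary(
    series: AccelSeries,
    min_duration_s: float = STATIONARY_MIN_S,
    sd_threshold_g: float = STATIONARY_SD_G,
    window_s: int = STATIONARY_WINDOW_S,
) -> list[tuple[float, float]]:
    """Locate quiet-stationary intervals for calibration.

    A 10-s window (stepped at 1 s from the first sample) is quiet when
    its vector-magnitude SD stays below ``sd_threshold_g``.  The union
    of quiet-window coverage is split into maximal intervals and those
    of at least ``min_duration_s`` are returned as (start, end) times in
    seconds since the anchor, sorted and non-overlapping.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    vm = series.vm
    sec, n_sec = _second_bins(series.t)
    cnt = np.bincount(sec, minlength=n_sec).astype(float)
    s1 = np.bincount(sec, weights=vm, minlength=n_sec)
    s2 = np.bincount(sec, weights=vm**2, minlength=n_sec)
    if n_sec < window_s:
        window_s = n_sec
    kern = np.ones(window_s)
    wc = np.convolve(cnt, kern, mode="valid")
    w1 = np.convolve(s1, kern, mode="valid")
    w2 = np.convolve(s2, kern, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        var = w2 / wc - (w1 / wc) ** 2
    sd = np.sqrt(np.clip(var, 0.0, None))
    # a window needs at least half its nominal samples to be judged quiet
    min_n = 0.5 * window_s * series.sample_rate
    quiet = (wc >= min_n) & (sd < sd_threshold_g)

    covered = np.zeros(n_sec, dtype=bool)
    for s, e in runs_of_true(quiet):
        covered[s : e - 1 + window_s] = True
    t0 = series.t[0]
    out = []
    for s, e in runs_of_true(covered):
        if e - s >= min_duration_s:
            out.append((t0 + s, t0 + e))
    return out


def estimate_calibration(
    series: AccelSeries,
    stationary: Sequence[tuple[float, float]],
    min_total_s: float = 60.0,
) -> CalibrationParams:
    """Estimate fixed bias, noise floor, and σ̄² from stationary intervals.

    bias is chosen so the median bias-corrected vector magnitude over
    stationary samples equals 1 g; noise_floor = 3 × stationary VM SD;
    σ̄² is the mean per-axis variance over stationary 1-s epochs.
    Raises :class:`CalibrationError` (with instruction to fall back to
    :data:`DEFAULT_CALIBRATION`) when under ``min_total_s`` of
    stationary data is available.
    """
    total = sum(e - s for s, e in stationary)
    if total < min_total_s:
        raise CalibrationError(
            f"only {total:.0f}s of stationary data (<{min_total_s:.0f}s); "
            "fall back to DEFAULT_CALIBRATION or configured defaults"
        )
    mask = np.zeros(len(series), dtype=bool)
    for s, e in stationary:
        mask |= (series.t >= s) & (series.t < e)
    vm = series.vm[mask]
    bias = float(np.median(vm) - 1.0)
    noise_floor = float(3.0 * np.std(vm))

    # per-axis variance over stationary 1-s epochs
    t = series.t[mask]
    sec = np.floor(t - t[0]).astype(np.int64)
    n_sec = int(sec[-1]) + 1
    cnt = np.bincount(sec, minlength=n_sec).astype(float)
    ok = cnt >= 2
    axis_vars = []
    for a in (series.x, series.y, series.z):
        av = a[mask]
        m = np.bincount(sec, weights=av, minlength=n_sec)
        q = np.bincount(sec, weights=av**2, minlength=n_sec)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = q / cnt - (m / cnt) ** 2
        axis_vars.append(np.clip(v[ok], 0.0, None))
    sigma_bar_sq = float(np.mean(axis_vars)) if ok.any() else 0.0
    return CalibrationParams(
        bias=bias,
        noise_floor=noise_floor,
        sigma_bar_sq=max(sigma_bar_sq, 1e-12),
    )


def epochize(series: AccelSeries, cal: CalibrationParams | None = None) -> EpochSeries:
    """Summarize an acceleration stream into calibrated 1-s epochs.

    Epoch boundaries are aligned to integer seconds from the first
    sample.  ``vm_bc`` applies the scalar bias and clamps deviations
    within the noise floor (and any residual negatives) to zero.
    """
    if cal is None:
        cal = DEFAULT_CALIBRATION
    if len(series) == 0:
        raise ValueError("empty series")
    sec, n_sec = _second_bins(series.t)
    cnt = np.bincount(sec, minlength=n_sec).astype(float)
    empty = cnt == 0

    def stats(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = np.bincount(sec, weights=a, minlength=n_sec)
        q = np.bincount(sec, weights=a**2, minlength=n_sec)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = m / cnt
            var = q / cnt - mean**2
        sd = np.sqrt(np.clip(var, 0.0, None))
        mean[empty] = np.nan
        sd[empty] = np.nan
        return mean, sd

    mx, sx = stats(series.x)
    my, sy = stats(series.y)
    mz, sz = stats(series.z)
    vm = series.vm
    vmm, vms = stats(vm)

    dev = vmm - 1.0 - cal.bias
    vm_bc = np.where(np.abs(dev) < cal.noise_floor, 0.0, np.maximum(dev, 0.0))
    vm_bc[empty] = np.nan

    return EpochSeries(
        epoch_start=series.t[0] + np.arange(n_sec, dtype=float),
        mean_x=mx, mean_y=my, mean_z=mz,
        sd_x=sx, sd_y=sy, sd_z=sz,
        vm_mean=vmm, vm_sd=vms, vm_bc=vm_bc,
        n_samples=cnt.astype(np.int64),
        anchor=series.anchor,
    )
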