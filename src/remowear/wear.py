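"""Non-wear detection from epoch-level axis variability.

A span is non-wear when per-axis variability stays below a threshold on
at least 2 of 3 axes over at least 90 contiguous minutes; detected spans
are padded by 15 min on each side to keep edge effects out of analysis.
Axis variability is evaluated over rolling 30-min sub-blocks stepping
1 min within the candidate span, using the law of total variance to
combine within-epoch variance and between-epoch mean drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from ._util import runs_of_true
from .accel import DEFAULT_ANCHOR, EpochSeries


class ConfigError(ValueError):
    """A non-wear parameter is non-positive or inconsistent."""


@dataclass
class NonwearSegment:
    """One detected non-wear span, in seconds since the record anchor.

    ``core_*`` bound the raw (unpadded) detection, which is always
    >= the minimum window; ``start/end`` include the padding, clamped
    to the record extent.
    """

    start: float
    end: float
    core_start: float
    core_end: float

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / 60.0

    @property
    def padded(self) -> bool:
        return self.start < self.core_start or self.end > self.core_end


@dataclass
class WearMask:
    """Per-epoch wear flag plus the derived non-wear segments."""

    epoch_start: np.ndarray
    wear: np.ndarray
    segments: list[NonwearSegment] = field(default_factory=list)
    anchor: datetime = field(default_factory=lambda: DEFAULT_ANCHOR)

    @property
    def nonwear_minutes(self) -> float:
        return float((~self.wear).sum()) / 60.0

    @property
    def wear_minutes(self) -> float:
        return float(self.wear.sum()) / 60.0

    def to_frame(self) -> pd.DataFrame:
        """3-column segment table (start, end, status) covering the record."""
        rows = []
        t0 = float(self.epoch_start[0])
        t_end = float(self.epoch_start[-1]) + 1.0
        cursor = t0
        for seg in self.segments:
            if seg.start > cursor:
                rows.append((cursor, seg.start, "wear"))
            rows.append((seg.start, seg.end, "nonwear"))
            cursor = seg.end
        if cursor < t_end:
            rows.append((cursor, t_end, "wear"))
        return pd.DataFrame(rows, columns=["start", "end", "status"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _subblock_quiet(
    epochs: EpochSeries, sd_threshold_g: float, subblock_min: int, min_axes: int
) -> tuple[np.ndarray, int]:
    """Quiet flag per 1-min-stepped 30-min sub-block start.

    A sub-block is quiet when, on >= ``min_axes`` axes, the combined SD
    (law of total variance over the sub-block's epochs) is below the
    threshold.  Sub-blocks with under half their epochs present are
    never quiet.
    """
    n_min = len(epochs) // 60
    w = subblock_min
    if n_min < w:
        return np.zeros(0, dtype=bool), n_min
    n_ep = n_min * 60
    present = (epochs.n_samples[:n_ep] > 0).reshape(n_min, 60)
    cnt_min = present.sum(axis=1).astype(float)

    quiet_axes = np.zeros(n_min - w + 1, dtype=np.int64)
    kern = np.ones(w)
    cnt_blk = np.convolve(cnt_min, kern, mode="valid")
    enough = cnt_blk >= 0.5 * w * 60
    for mean, sd in (
        (epochs.mean_x, epochs.sd_x),
        (epochs.mean_y, epochs.sd_y),
        (epochs.mean_z, epochs.sd_z),
    ):
        m = np.where(present, np.nan_to_num(mean[:n_ep].reshape(n_min, 60)), 0.0)
        v = np.where(present, np.nan_to_num(sd[:n_ep].reshape(n_min, 60)) ** 2, 0.0)
        s1 = np.convolve((m).sum(axis=1), kern, mode="valid")
        s2 = np.convolve((m**2 + v).sum(axis=1), kern, mode="valid")
        with np.errstate(invalid="ignore", divide="ignore"):
            var_tot = s2 / cnt_blk - (s1 / cnt_blk) ** 2
        sd_blk = np.sqrt(np.clip(var_tot, 0.0, None))
        quiet_axes += (enough & (sd_blk < sd_threshold_g)).astype(np.int64)
    return quiet_axes >= min_axes, n_min


def detect_nonwear(
    epochs: EpochSeries,
    sd_threshold_g: float = 0.013,
    min_window_min: int = 90,
    min_axes: int = 2,
    pad_min: int = 15,
    subblock_min: int = 30,
) -> WearMask:
    """Flag non-wear spans and return a padded wear mask.

    A contiguous span of at least ``min_window_min`` minutes is non-wear
    when every 30-min sub-block within it (stepping 1 min) is quiet on
    >= ``min_axes`` axes.  Each detected span is extended by ``pad_min``
    on each side (clamped to the record) and overlapping padded spans
    are merged.  Records shorter than the minimum window return all-wear.
    """
    if sd_threshold_g <= 0 or min_window_min <= 0 or pad_min < 0 or subblock_min <= 0:
        raise ConfigError("non-wear thresholds must be positive (pad_min >= 0)")
    if subblock_min > min_window_min:
        raise ConfigError("subblock_min must not exceed min_window_min")

    n_ep = len(epochs)
    wear = np.ones(n_ep, dtype=bool)
    t0 = float(epochs.epoch_start[0])
    record_end = t0 + n_ep  # 1-s epochs

    if n_ep < min_window_min * 60:
        return WearMask(epoch_start=epochs.epoch_start, wear=wear, segments=[], anchor=epochs.anchor)

    quiet, n_min = _subblock_quiet(epochs, sd_threshold_g, subblock_min, min_axes)
    need = min_window_min - subblock_min + 1  # consecutive quiet sub-block starts

    cores: list[tuple[float, float]] = []
    for s, e in runs_of_true(quiet):
        span_min = (e - s - 1) + subblock_min
        if e - s >= need and span_min >= min_window_min:
            cores.append((t0 + s * 60.0, t0 + (s + span_min) * 60.0))

    segments: list[NonwearSegment] = []
    for cs, ce in cores:
        ps = max(t0, cs - pad_min * 60.0)
        pe = min(record_end, ce + pad_min * 60.0)
        if segments and ps <= segments[-1].end:
            prev = segments[-1]
            segments[-1] = NonwearSegment(
                start=prev.start, end=max(prev.end, pe),
                core_start=prev.core_start, core_end=max(prev.core_end, ce),
            )
        else:
            segments.append(NonwearSegment(start=ps, end=pe, core_start=cs, core_end=ce))

    for seg in segments:
        i0 = int(np.searchsorted(epochs.epoch_start, seg.start, side="left"))
        i1 = int(np.searchsorted(epochs.epoch_start, seg.end, side="left"))
        wear[i0:i1] = False

    return WearMask(epoch_start=epochs.epoch_start, wear=wear, segments=segments, anchor=epochs.anchor)
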