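"""Per-24-h frailty-aligned mobility metrics and 48-h session summaries.

Each initiated monitoring session spans 48 h from the moment the wearer
pressed "Start monitoring" and splits into up to two 24-h intervals
anchored at that initiation time (not calendar midnight).  Per interval
the pipeline reports total steps, cadence (90th-percentile steps/min
over stepping minutes — "best pace"), the longest walking bout (LWB,
capped at 2 h), and the daytime Activity Index, then applies the
validity rules: at most 1.5 h non-wear and at least 300 detected steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from ._util import merge_intervals
from .accel import CalibrationParams, EpochSeries
from .steps import StepEvents, steps_per_minute
from .wear import WearMask

EXCESS_NONWEAR = "excess_nonwear"
TOO_FEW_STEPS = "too_few_steps"
INSUFFICIENT_COVERAGE = "insufficient_coverage"

DAY_WINDOW = (7, 19)  # local-clock daytime hours [07:00, 19:00)
LWB_CAP_S = 7200.0
LWB_GAP_S = 3.0


class ConfigError(ValueError):
    pass


@dataclass
class DailyMetrics:
    """Metrics and validity flags for one session-relative 24-h interval."""

    interval_id: str
    start: datetime
    end: datetime
    total_steps: int = 0
    cadence_p90: float = 0.0
    cadence_defined: bool = False
    lwb_steps: int = 0
    lwb_duration_s: float = 0.0
    aind_daily: float = float("nan")
    aind_coverage: float = 0.0
    aind_missing: bool = True
    nonwear_h: float = 0.0
    n_epochs: int = 0
    valid: bool = False
    invalid_reasons: set = field(default_factory=set)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["start"] = self.start.isoformat()
        d["end"] = self.end.isoformat()
        d["invalid_reasons"] = sorted(self.invalid_reasons)
        return d


@dataclass
class WindowSummary:
    """One 48-h monitoring session: up to two 24-h interval summaries.

    ``retained_aind`` is the larger of the available 24-h Activity
    Index summaries; ``n_valid_intervals`` counts step-validity passes.
    """

    session_id: str
    intervals: list[DailyMetrics]
    retained_aind: float
    n_valid_intervals: int

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "retained_aind": self.retained_aind,
            "n_valid_intervals": self.n_valid_intervals,
            "intervals": [m.to_dict() for m in self.intervals],
        }


def split_session(
    session_start: datetime, duration_h: float = 48.0, interval_h: float = 24.0
) -> list[tuple[datetime, datetime]]:
    """Split a 48-h session (from initiation, not midnight) into 24-h intervals."""
    n = int(round(duration_h / interval_h))
    return [
        (
            session_start + timedelta(hours=interval_h * k),
            session_start + timedelta(hours=interval_h * (k + 1)),
        )
        for k in range(n)
    ]


def compute_cadence(per_minute_counts: np.ndarray) -> tuple[float, bool]:
    """90th-percentile steps/min over minutes with >= 1 detected step.

    Returns (cadence, defined); an interval with no stepping minutes
    reports cadence 0 with ``defined=False``.
    """
    counts = np.asarray(per_minute_counts, dtype=float)
    stepping = counts[np.isfinite(counts) & (counts >= 1)]
    if len(stepping) == 0:
        return 0.0, False
    return float(np.percentile(stepping, 90, method="linear")), True


def compute_lwb(
    step_times: np.ndarray, gap_s: float = LWB_GAP_S, cap_s: float = LWB_CAP_S
) -> tuple[int, float]:
    """Longest walking bout: (steps, duration_s), 2-h cap from bout start.

    A bout is a maximal run of steps with inter-step gaps <= ``gap_s``.
    Steps beyond ``cap_s`` after the bout's first step are not counted
    and the reported duration is capped at ``cap_s``.  The LWB is the
    bout with the most (capped) steps; ties resolve to the earliest.
    """
    t = np.sort(np.asarray(step_times, dtype=float))
    if len(t) == 0:
        return 0, 0.0
    breaks = np.flatnonzero(np.diff(t) > gap_s)
    bounds = np.concatenate(([0], breaks + 1, [len(t)]))
    best = (0, 0.0)
    for i in range(len(bounds) - 1):
        bout = t[bounds[i] : bounds[i + 1]]
        kept = bout[(bout - bout[0]) < cap_s]
        n = len(kept)
        dur = min(float(bout[-1] - bout[0]), cap_s)
        if n > best[0]:
            best = (n, dur)
    return best


def compute_aind(
    epochs: EpochSeries,
    cal: CalibrationParams,
    wear: WearMask,
    interval: tuple[datetime, datetime],
    day_window: tuple[int, int] = DAY_WINDOW,
    min_coverage: float = 0.5,
) -> tuple[float, float, bool]:
    """Daytime Activity Index summary for one 24-h interval.

    Per 1-s epoch, AI = sqrt(max(0, mean_axes((σ²_axis − σ̄²) / σ̄²)));
    the daily value sums AI over worn epochs whose local-clock hour lies
    in ``day_window`` (default 07:00–19:00) and inside the interval.
    Non-wear and missing epochs contribute 0.  Returns
    (aind_daily, coverage, missing): coverage is the fraction of daytime
    seconds in the interval with a worn, sampled epoch, and the summary
    is flagged missing when coverage < ``min_coverage``.
    """
    if cal.sigma_bar_sq <= 0:
        raise ConfigError("sigma_bar_sq must be > 0")
    s0 = (interval[0] - epochs.anchor).total_seconds()
    s1 = (interval[1] - epochs.anchor).total_seconds()
    in_iv = (epochs.epoch_start >= s0) & (epochs.epoch_start < s1)
    hours = epochs.local_hours()
    daytime = (hours >= day_window[0]) & (hours < day_window[1])
    present = epochs.n_samples > 0
    worn = wear.wear if len(wear.wear) == len(epochs) else np.ones(len(epochs), dtype=bool)

    var = np.vstack([epochs.sd_x, epochs.sd_y, epochs.sd_z]) ** 2
    rel = (var - cal.sigma_bar_sq) / cal.sigma_bar_sq
    ai = np.sqrt(np.clip(np.nanmean(rel, axis=0), 0.0, None))
    ai = np.where(present, ai, 0.0)

    use = in_iv & daytime & worn & present
    aind = float(np.nansum(ai[use]))

    total_daytime_s = _daytime_seconds(interval, day_window)
    coverage = float(use.sum()) / total_daytime_s if total_daytime_s > 0 else 0.0
    return aind, coverage, coverage < min_coverage


def _daytime_seconds(interval: tuple[datetime, datetime], day_window: tuple[int, int]) -> float:
    """Seconds of local-clock daytime within an arbitrary interval."""
    start, end = interval
    total = 0.0
    day = start.replace(hour=0, minute=0, second=0, microsecond=0)
    while day < end:
        w0 = day + timedelta(hours=day_window[0])
        w1 = day + timedelta(hours=day_window[1])
        lo, hi = max(start, w0), min(end, w1)
        if hi > lo:
            total += (hi - lo).total_seconds()
        day += timedelta(days=1)
    return total


def filter_valid(
    metrics: DailyMetrics, max_nonwear_h: float = 1.5, min_steps: int = 300
) -> DailyMetrics:
    """Apply interval validity rules (boundaries inclusive).

    Valid iff non-wear <= 1.5 h AND total steps >= 300 AND the interval
    had any coverage; reasons are recorded on the metrics object.
    """
    reasons = set(metrics.invalid_reasons)
    reasons.discard(EXCESS_NONWEAR)
    reasons.discard(TOO_FEW_STEPS)
    if metrics.nonwear_h > max_nonwear_h:
        reasons.add(EXCESS_NONWEAR)
    if metrics.total_steps < min_steps:
        reasons.add(TOO_FEW_STEPS)
    metrics.invalid_reasons = reasons
    metrics.valid = not reasons
    return metrics


def summarize_window(session_id: str, intervals: list[DailyMetrics]) -> WindowSummary:
    """Retain the larger 24-h Activity Index and count valid intervals."""
    if not intervals:
        raise ValueError("at least one interval required")
    ainds = [m.aind_daily for m in intervals if not m.aind_missing and np.isfinite(m.aind_daily)]
    retained = max(ainds) if ainds else float("nan")
    n_valid = sum(1 for m in intervals if m.valid)
    return WindowSummary(
        session_id=session_id, intervals=intervals, retained_aind=retained, n_valid_intervals=n_valid
    )


def summarize_session(
    session_id: str,
    session_start: datetime,
    epochs: EpochSeries,
    steps: StepEvents,
    wear: WearMask,
    cal: CalibrationParams,
    *,
    max_nonwear_h: float = 1.5,
    min_steps: int = 300,
    gap_s: float = LWB_GAP_S,
    cap_s: float = LWB_CAP_S,
    day_window: tuple[int, int] = DAY_WINDOW,
    aind_min_coverage: float = 0.5,
) -> WindowSummary:
    """Full per-session metric computation over the two 24-h intervals."""
    out: list[DailyMetrics] = []
    for k, (iv_start, iv_end) in enumerate(split_session(session_start)):
        s0 = (iv_start - epochs.anchor).total_seconds()
        s1 = (iv_end - epochs.anchor).total_seconds()
        in_iv = (epochs.epoch_start >= s0) & (epochs.epoch_start < s1)
        n_ep = int((in_iv & (epochs.n_samples > 0)).sum())

        dm = DailyMetrics(
            interval_id=f"{session_id}/{k}", start=iv_start, end=iv_end, n_epochs=n_ep
        )
        if n_ep == 0:
            dm.invalid_reasons.add(INSUFFICIENT_COVERAGE)
            out.append(filter_valid(dm, max_nonwear_h, min_steps))
            continue

        st = steps.times[(steps.times >= s0) & (steps.times < s1)]
        dm.total_steps = int(len(st))

        spm = steps_per_minute(
            StepEvents(st, np.zeros(len(st)), np.zeros(len(st), dtype=int), steps.anchor),
            span=(max(s0, float(epochs.epoch_start[0])), min(s1, float(epochs.epoch_start[-1]) + 1)),
            wear=wear,
        )
        dm.cadence_p90, dm.cadence_defined = compute_cadence(spm["steps"].to_numpy())
        dm.lwb_steps, dm.lwb_duration_s = compute_lwb(st, gap_s=gap_s, cap_s=cap_s)

        nonwear = merge_intervals(
            [(max(seg.start, s0), min(seg.end, s1)) for seg in wear.segments]
        )
        dm.nonwear_h = sum(e - s for s, e in nonwear) / 3600.0

        dm.aind_daily, dm.aind_coverage, dm.aind_missing = compute_aind(
            epochs, cal, wear, (iv_start, iv_end), day_window, aind_min_coverage
        )
        out.append(filter_valid(dm, max_nonwear_h, min_steps))
    return summarize_window(session_id, out)


def metrics_frame(summaries: list[WindowSummary], participant_id: str = "") -> pd.DataFrame:
    """One row per 24-h interval across sessions, CSV-ready."""
    rows = []
    for ws in summaries:
        for m in ws.intervals:
            d = m.to_dict()
            d["session_id"] = ws.session_id
            d["participant_id"] = participant_id
            d["invalid_reasons"] = ";".join(d["invalid_reasons"])
            rows.append(d)
    return pd.DataFrame(rows)
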