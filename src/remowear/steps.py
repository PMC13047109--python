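"""Two-stage step detection for 10 Hz wrist accelerometry.

Stage one labels non-overlapping short windows as moving / not moving
from time-domain and band-power features of the triaxial signal.  Stage
two band-passes the vector magnitude to the gait band (0.6–2.5 Hz,
zero-phase so peak times stay unbiased), finds local maxima above an
adaptive amplitude threshold inside moving windows, and keeps maximal
runs of at least four peaks whose successive intervals are physiologic
(0.33–1.67 s) and regular (pairwise spread <= 0.35 s).  One step is
emitted per kept peak; steps inside non-wear spans are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import signal as sps

from .accel import DEFAULT_ANCHOR, AccelSeries
from .wear import WearMask

GAIT_BAND_HZ = (0.6, 2.5)
CONTRACT_RATE_HZ = 10.0


class RateError(ValueError):
    """Input sample rate is not the 10 Hz contract rate."""


@dataclass
class MotionWindows:
    """Non-overlapping fixed-length windows labelled moving / not moving."""

    window_start: np.ndarray  # seconds since anchor
    window_len_s: float
    moving: np.ndarray  # bool per window
    features: pd.DataFrame
    anchor: datetime = field(default_factory=lambda: DEFAULT_ANCHOR)

    def __len__(self) -> int:
        return len(self.window_start)


@dataclass
class StepEvents:
    """Detected step timestamps (s since anchor) with peak amplitudes (g)."""

    times: np.ndarray
    amplitudes: np.ndarray
    window_index: np.ndarray
    anchor: datetime = field(default_factory=lambda: DEFAULT_ANCHOR)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.times, "amplitude": self.amplitudes, "window": self.window_index}
        )

    def to_csv(self, path) -> None:
        self.to_frame()[["timestamp", "amplitude"]].to_csv(path, index=False)


def classify_motion(
    series: AccelSeries,
    window_len_s: float = 5.0,
    moving_sd_threshold_g: float = 0.030,
    band_hz: tuple[float, float] = GAIT_BAND_HZ,
    band_frac: float = 0.5,
) -> MotionWindows:
    """Label fixed windows moving iff VM SD and gait-band dominance agree.

    moving requires VM SD >= ``moving_sd_threshold_g`` AND the dominant
    (non-DC) frequency inside ``band_hz`` AND at least ``band_frac`` of
    non-DC spectral power in that band.  A trailing partial window is
    labelled not moving.
    """
    fs = series.sample_rate
    n_win = int(window_len_s * fs)
    if len(series) < n_win:
        raise ValueError("need at least one full window of data")
    n_full = len(series) // n_win
    vm = series.vm[: n_full * n_win].reshape(n_full, n_win)

    sd = vm.std(axis=1)
    rng = vm.max(axis=1) - vm.min(axis=1)
    ax_sd = {
        f"sd_{name}": a[: n_full * n_win].reshape(n_full, n_win).std(axis=1)
        for name, a in (("x", series.x), ("y", series.y), ("z", series.z))
    }

    spec = np.abs(np.fft.rfft(vm - vm.mean(axis=1, keepdims=True), axis=1)) ** 2
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    power = spec[:, 1:]  # exclude DC
    f_nz = freqs[1:]
    dom = f_nz[np.argmax(power, axis=1)]
    in_band = (f_nz >= band_hz[0]) & (f_nz <= band_hz[1])
    tot = power.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, power[:, in_band].sum(axis=1) / tot, 0.0)

    moving = (sd >= moving_sd_threshold_g) & (dom >= band_hz[0]) & (dom <= band_hz[1]) & (frac >= band_frac)
    feats = pd.DataFrame({"vm_sd": sd, "vm_range": rng, "dom_freq_hz": dom, "band_frac": frac, **ax_sd})
    starts = series.t[0] + np.arange(n_full) * window_len_s
    return MotionWindows(
        window_start=starts, window_len_s=window_len_s, moving=moving,
        features=feats, anchor=series.anchor,
    )


def _regular_runs(
    peak_t: np.ndarray,
    min_run: int,
    interval_bounds: tuple[float, float],
    max_spread: float,
) -> list[np.ndarray]:
    """Split peaks into maximal regular runs; keep runs of >= min_run peaks."""
    runs: list[np.ndarray] = []
    cur: list[int] = []
    intervals: list[float] = []
    lo, hi = interval_bounds
    for i, t in enumerate(peak_t):
        if not cur:
            cur = [i]
            continue
        dt = t - peak_t[cur[-1]]
        cand = intervals + [dt]
        if lo <= dt <= hi and (max(cand) - min(cand)) <= max_spread:
            cur.append(i)
            intervals = cand
        else:
            if len(cur) >= min_run:
                runs.append(np.array(cur))
            cur, intervals = [i], []
    if len(cur) >= min_run:
        runs.append(np.array(cur))
    return runs


def detect_steps(
    series: AccelSeries,
    motion: MotionWindows,
    wear: WearMask | None = None,
    *,
    band_hz: tuple[float, float] = GAIT_BAND_HZ,
    amp_floor_g: float = 0.050,
    amp_rms_factor: float = 0.6,
    min_run: int = 4,
    interval_bounds: tuple[float, float] = (0.33, 1.67),
    max_interval_spread: float = 0.35,
    resample: bool = False,
) -> StepEvents:
    """Detect steps as regular, physiologically timed peaks in moving windows.

    The contract rate is 10 Hz; other rates raise :class:`RateError`
    unless ``resample=True`` enables linear resampling onto a 10 Hz grid.
    The per-window amplitude threshold is
    ``max(amp_floor_g, amp_rms_factor × RMS of the band-passed window)``.
    """
    fs = series.sample_rate
    if abs(fs - CONTRACT_RATE_HZ) > 1e-9:
        if not resample:
            raise RateError(f"sample rate {fs} Hz != contract 10 Hz (pass resample=True)")
        t10 = np.arange(series.t[0], series.t[-1], 1.0 / CONTRACT_RATE_HZ)
        series = AccelSeries(
            t=t10,
            x=np.interp(t10, series.t, series.x),
            y=np.interp(t10, series.t, series.y),
            z=np.interp(t10, series.t, series.z),
            sample_rate=CONTRACT_RATE_HZ,
            device_id=series.device_id,
            anchor=series.anchor,
        )
        fs = CONTRACT_RATE_HZ

    vm = series.vm
    sos = sps.butter(2, band_hz, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, vm - vm.mean())

    # per-window adaptive threshold over the band-passed signal
    n_win = int(motion.window_len_s * fs)
    win_of_sample = np.minimum(np.arange(len(vm)) // n_win, len(motion) - 1)
    peaks, _ = sps.find_peaks(filt, distance=max(2, int(round(fs * interval_bounds[0]))))
    if len(peaks) == 0:
        return StepEvents(np.array([]), np.array([]), np.array([], dtype=int), series.anchor)

    pk_win = win_of_sample[peaks]
    in_full_win = peaks < len(motion) * n_win
    is_moving = np.zeros(len(peaks), dtype=bool)
    is_moving[in_full_win] = motion.moving[pk_win[in_full_win]]

    thr = np.empty(len(peaks))
    for w in np.unique(pk_win):
        seg = filt[w * n_win : (w + 1) * n_win]
        rms = np.sqrt(np.mean(seg**2)) if len(seg) else 0.0
        thr[pk_win == w] = max(amp_floor_g, amp_rms_factor * rms)

    keep = is_moving & (filt[peaks] >= thr)
    peaks = peaks[keep]
    pk_win = pk_win[keep]
    peak_t = series.t[peaks]

    idx_runs = _regular_runs(peak_t, min_run, interval_bounds, max_interval_spread)
    if not idx_runs:
        return StepEvents(np.array([]), np.array([]), np.array([], dtype=int), series.anchor)
    sel = np.concatenate(idx_runs)
    sel.sort()
    times = peak_t[sel]
    amps = filt[peaks[sel]]
    wins = pk_win[sel]

    if wear is not None and len(wear.epoch_start):
        ep_idx = np.searchsorted(wear.epoch_start, times, side="right") - 1
        ep_idx = np.clip(ep_idx, 0, len(wear.wear) - 1)
        worn = wear.wear[ep_idx]
        times, amps, wins = times[worn], amps[worn], wins[worn]

    if len(times) > 1:
        assert np.all(np.diff(times) >= interval_bounds[0] - 1e-9), "step spacing violated"
    return StepEvents(times=times, amplitudes=amps, window_index=wins, anchor=series.anchor)


def steps_per_minute(
    steps: StepEvents,
    span: tuple[float, float],
    wear: WearMask | None = None,
) -> pd.DataFrame:
    """Bin step events into local-clock minutes over ``span`` (seconds).

    Minute boundaries align to the anchor clock (the anchor is assumed
    minute-aligned).  ``observed`` distinguishes minutes with data
    (any wear epoch) from minutes with none; unobserved minutes carry
    NaN counts rather than zero.
    """
    t0, t1 = span
    m0 = int(np.floor(t0 / 60.0))
    m1 = int(np.ceil(t1 / 60.0))
    edges = np.arange(m0, m1 + 1) * 60.0
    counts = np.histogram(steps.times, bins=edges)[0].astype(float)

    observed = np.ones(len(counts), dtype=bool)
    if wear is not None and len(wear.epoch_start):
        ep_min = np.floor(wear.epoch_start / 60.0).astype(np.int64)
        observed = np.zeros(len(counts), dtype=bool)
        worn_minutes = np.unique(ep_min[wear.wear])
        idx = worn_minutes - m0
        idx = idx[(idx >= 0) & (idx < len(counts))]
        observed[idx] = True
    counts[~observed] = np.nan
    return pd.DataFrame({"minute_start": edges[:-1], "steps": counts, "observed": observed})
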