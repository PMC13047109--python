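"""End-to-end accelerometry processing: raw counts to session summaries."""

from __future__ import annotations

from datetime import datetime

from . import accel, steps as steps_mod, wear as wear_mod
from .config import RunConfig
from .metrics import WindowSummary, summarize_session


def process_raw_session(
    raw: accel.RawSampleSeries,
    session_start: datetime | None = None,
    session_id: str = "session-0",
    config: RunConfig | None = None,
) -> WindowSummary:
    """Run ingest -> calibration -> wear -> steps -> metrics for one session.

    ``session_start`` defaults to the recording anchor (initiation and
    recording start coincide for prompted sessions).  Falls back to the
    configured default calibration when the recording holds no usable
    quiet-stationary interval.
    """
    cfg = config or RunConfig()
    acc = accel.counts_to_g(raw)
    stationary = accel.find_stationary(
        acc,
        min_duration_s=cfg.calibration.stationary_min_duration_s,
        sd_threshold_g=cfg.calibration.stationary_sd_threshold_g,
        window_s=cfg.calibration.stationary_window_s,
    )
    try:
        cal = accel.estimate_calibration(acc, stationary)
    except accel.CalibrationError:
        cal = accel.CalibrationParams(
            bias=cfg.calibration.default_bias_g,
            noise_floor=cfg.calibration.default_noise_floor_g,
            sigma_bar_sq=cfg.calibration.default_sigma_bar_sq,
        )
    epochs = accel.epochize(acc, cal)
    wear = wear_mod.detect_nonwear(
        epochs,
        sd_threshold_g=cfg.wear.sd_threshold_g,
        min_window_min=cfg.wear.min_window_min,
        min_axes=cfg.wear.min_axes,
        pad_min=cfg.wear.pad_min,
        subblock_min=cfg.wear.subblock_min,
    )
    motion = steps_mod.classify_motion(
        acc,
        window_len_s=cfg.steps.window_len_s,
        moving_sd_threshold_g=cfg.steps.moving_sd_threshold_g,
        band_hz=(cfg.steps.band_low_hz, cfg.steps.band_high_hz),
        band_frac=cfg.steps.band_frac,
    )
    step_events = steps_mod.detect_steps(
        acc,
        motion,
        wear,
        band_hz=(cfg.steps.band_low_hz, cfg.steps.band_high_hz),
        amp_floor_g=cfg.steps.amp_floor_g,
        amp_rms_factor=cfg.steps.amp_rms_factor,
        min_run=cfg.steps.min_run,
        interval_bounds=(cfg.steps.interval_min_s, cfg.steps.interval_max_s),
        max_interval_spread=cfg.steps.max_interval_spread_s,
        resample=cfg.steps.resample,
    )
    return summarize_session(
        session_id,
        session_start or raw.anchor,
        epochs,
        step_events,
        wear,
        cal,
        max_nonwear_h=cfg.metrics.max_nonwear_h,
        min_steps=cfg.metrics.min_steps,
        gap_s=cfg.metrics.lwb_gap_s,
        cap_s=cfg.metrics.lwb_cap_s,
        day_window=(cfg.metrics.day_start_hour, cfg.metrics.day_end_hour),
        aind_min_coverage=cfg.metrics.aind_min_coverage,
    )
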