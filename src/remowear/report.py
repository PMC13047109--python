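"""Engagement and adherence accounting from a prompt ledger.

Two denominators are reported and never conflated:

* **end-to-end completeness** — completed / scheduled, device failures
  kept in the denominator (the per-participant completeness table);
* **participant-attributable adherence** — completed /
  (scheduled − device-failed), isolating participant behavior.

The study-level engagement criterion asks whether enough participants
completed >= 50% of prompted tasks, pooled across modalities, within
every 4-week block of the engagement window.  Usability uses the
System Usability Scale (SUS, 0–100); geriatric-assessment change flags
apply prespecified decline thresholds per instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .prompts import MODALITIES, IntegrityError, PromptLedger


@dataclass
class EngagementBlockResult:
    participant_id: str
    block: int
    scheduled: int
    completed: int
    fraction: float
    met: bool


@dataclass
class GaChange:
    """Prespecified geriatric-assessment change flags (week 12 vs baseline)."""

    flags: set = field(default_factory=set)
    unevaluable: set = field(default_factory=set)


def tabulate_completeness(ledger: PromptLedger) -> pd.DataFrame:
    """Per-participant completeness counts by modality plus a totals row.

    Columns per modality: ``scheduled``, ``completed``,
    ``incomplete_participant`` (expired), ``incomplete_device``
    (device-failed) and ``pct`` (completed/scheduled, half-up integer;
    <NA> when nothing was scheduled).  Raises :class:`IntegrityError`
    naming the offending row if conservation fails.
    """
    df = ledger.to_frame()
    pids = sorted(df["participant_id"].unique()) if not df.empty else []
    rows = []
    for pid in pids + ["Total"]:
        sub = df if pid == "Total" else df[df["participant_id"] == pid]
        row: dict = {"participant_id": pid}
        for mod in MODALITIES:
            g = sub[sub["modality"] == mod]
            sched = len(g)
            comp = int((g["status"] == "completed").sum())
            exp = int((g["status"] == "expired").sum())
            dev = int((g["status"] == "device_failed").sum())
            if comp + exp + dev != sched:
                raise IntegrityError(
                    f"row {pid}/{mod}: scheduled {sched} != completed {comp} "
                    f"+ participant {exp} + device {dev}"
                )
            row[f"{mod}_scheduled"] = sched
            row[f"{mod}_completed"] = comp
            row[f"{mod}_incomplete_participant"] = exp
            row[f"{mod}_incomplete_device"] = dev
            row[f"{mod}_pct"] = round_half_up(100.0 * comp / sched) if sched else pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def participant_attributable(ledger: PromptLedger, modality: str) -> float:
    """completed / (scheduled − device-failed) for one modality; NaN if empty."""
    df = ledger.to_frame()
    g = df[df["modality"] == modality]
    denom = len(g) - int((g["status"] == "device_failed").sum())
    if denom == 0:
        return float("nan")
    return float((g["status"] == "completed").sum()) / denom


def block_engagement(
    ledger: PromptLedger,
    block_days: int = 28,
    threshold: float = 0.5,
    min_participants: int = 6,
    n_blocks: int | None = None,
) -> tuple[pd.DataFrame, bool]:
    """Per-participant 4-week-block engagement and the study criterion.

    Blocks are anchored at each participant's deployment date; prompts
    pool across modalities; device-failed prompts leave the denominator
    (engagement measures participant behavior).  A trailing partial
    block is dropped from the criterion when its scheduled prompts span
    under 7 days.  The criterion is met iff >= ``min_participants``
    participants reach the threshold in **every** retained block.
    """
    df = ledger.to_frame()
    if df.empty:
        return pd.DataFrame(columns=[
            "participant_id", "block", "scheduled", "completed", "fraction", "met"
        ]), False
    df = df.copy()
    df["issued_dt"] = pd.to_datetime(df["issued_at"], format="ISO8601")
    rows: list[EngagementBlockResult] = []
    all_met: dict[str, bool] = {}
    for pid, grp in df.groupby("participant_id"):
        start = ledger.deployments.get(pid, grp["issued_dt"].min())
        offset_d = (grp["issued_dt"] - pd.Timestamp(start)).dt.total_seconds() / 86400.0
        blk = np.floor(offset_d / block_days).astype(int)
        last = int(blk.max()) if n_blocks is None else n_blocks - 1
        met_all = True
        for b in range(last + 1):
            g = grp[blk == b]
            span_d = (
                (g["issued_dt"].max() - g["issued_dt"].min()).total_seconds() / 86400.0
                if len(g) else 0.0
            )
            denom = int((g["status"] != "device_failed").sum())
            comp = int((g["status"] == "completed").sum())
            frac = comp / denom if denom else float("nan")
            met = bool(denom and frac >= threshold)
            partial_tail = b == last and n_blocks is None and span_d < 7.0
            rows.append(EngagementBlockResult(pid, b, denom, comp, frac, met))
            if denom and not partial_tail:
                met_all = met_all and met
        all_met[pid] = met_all
    table = pd.DataFrame([r.__dict__ for r in rows])
    criterion = sum(all_met.values()) >= min_participants
    return table, bool(criterion)


def sus_score(items: Sequence[float]) -> float:
    """System Usability Scale score from ten 1–5 item responses.

    score = 2.5 × Σ contributions, where odd-numbered items (1st, 3rd,
    ...) contribute (value − 1) and even-numbered items (5 − value).
    Missing or out-of-range items raise; no imputation.
    """
    items = list(items)
    if len(items) != 10:
        raise ValueError(f"SUS requires exactly 10 items, got {len(items)}")
    total = 0.0
    for i, v in enumerate(items):
        if v is None or not (1 <= v <= 5):
            raise ValueError(f"SUS item {i + 1} out of range 1-5: {v!r}")
        total += (v - 1) if i % 2 == 0 else (5 - v)
    return 2.5 * total


#: GA instruments and the direction of concerning change.
GA_INSTRUMENTS = ("g8", "carg", "cirsg", "g8_srh", "fact_g")


def ga_change_flags(baseline: Mapping[str, float], week12: Mapping[str, float]) -> GaChange:
    """Prespecified decline flags: G8 decline >= 1, CARG increase >= 1,
    CIRS-G increase >= 1, any G8-SRH downgrade, FACT-G decline > 3.

    An instrument missing either timepoint is recorded unevaluable and
    contributes no flag.
    """
    out = GaChange()

    def get(d: Mapping[str, float], key: str):
        v = d.get(key)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    rules = {
        "g8_decline": ("g8", lambda b, w: b - w >= 1),
        "carg_increase": ("carg", lambda b, w: w - b >= 1),
        "cirsg_increase": ("cirsg", lambda b, w: w - b >= 1),
        "g8_srh_downgrade": ("g8_srh", lambda b, w: w < b),
        "fact_g_decline": ("fact_g", lambda b, w: b - w > 3),
    }
    for flag, (key, rule) in rules.items():
        b, w = get(baseline, key), get(week12, key)
        if b is None or w is None:
            out.unevaluable.add(key)
        elif rule(b, w):
            out.flags.add(flag)
    return out


def max_recoverable_intervals(
    initiations: Mapping[str, int] | int, per_session: int = 2
) -> int:
    """Maximum recoverable 24-h intervals: two per initiated 48-h session."""
    n = initiations if isinstance(initiations, int) else sum(initiations.values())
    return per_session * int(n)
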