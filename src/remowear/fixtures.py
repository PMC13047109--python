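"""Packaged study fixtures: the per-participant prompt-completion table
and the full-deployment watch-initiation counts.

``COMPLETION_TABLE`` transcribes the deployment's per-participant
prompt accounting over the 12-week engagement window — scheduled /
completed / incomplete (participant, device) counts for the four
modalities.  :func:`table2_ledger` materializes it as a
:class:`~remowear.prompts.PromptLedger` with synthesized timestamps
consistent with the counts, so every reporting operation can run
against it.
"""

from __future__ import annotations

from datetime import datetime, timedelta

from .prompts import DeviceFailureEvent, PromptInstance, PromptLedger

#: Per-participant counts over the 84-day engagement window.
#: Per modality: (scheduled, completed, incomplete_participant, incomplete_device).
COMPLETION_TABLE: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "2ba4": {"srh": (16, 16, 0, 0), "symptom": (5, 5, 0, 0), "scale": (11, 11, 0, 0), "watch": (6, 4, 2, 0)},
    "1821": {"srh": (11, 9, 2, 0), "symptom": (10, 9, 1, 0), "scale": (11, 9, 2, 0), "watch": (5, 5, 0, 0)},
    "50a8": {"srh": (16, 16, 0, 0), "symptom": (1, 1, 0, 0), "scale": (11, 11, 0, 0), "watch": (6, 5, 1, 0)},
    "996d": {"srh": (13, 10, 3, 0), "symptom": (1, 1, 0, 0), "scale": (10, 8, 2, 0), "watch": (4, 3, 0, 1)},
    "CFD1": {"srh": (11, 9, 2, 0), "symptom": (5, 3, 2, 0), "scale": (9, 8, 1, 0), "watch": (7, 5, 2, 0)},
    "5cd9": {"srh": (14, 12, 2, 0), "symptom": (6, 6, 0, 0), "scale": (11, 9, 2, 0), "watch": (6, 2, 0, 4)},
    "E5b2": {"srh": (17, 15, 2, 0), "symptom": (7, 4, 3, 0), "scale": (11, 8, 3, 0), "watch": (7, 2, 2, 3)},
    "03a7": {"srh": (12, 7, 5, 0), "symptom": (6, 6, 0, 0), "scale": (11, 6, 5, 0), "watch": (7, 3, 4, 0)},
    "2863": {"srh": (9, 9, 0, 0), "symptom": (8, 7, 1, 0), "scale": (9, 8, 1, 0), "watch": (9, 8, 1, 0)},
    "7d78": {"srh": (7, 5, 2, 0), "symptom": (4, 4, 0, 0), "scale": (6, 5, 1, 0), "watch": (5, 3, 2, 0)},
}

#: Participant who initiated watch sessions but never wore the device;
#: excluded from accelerometry-derived analyses.
NON_WEAR_PARTICIPANT = "1821"

#: Synthetic allocation of the 40 full-deployment watch-session
#: initiations across the nine analyzable participants.  Only the total
#: (40 sessions -> 80 recoverable 24-h intervals) is study-reported;
#: the per-participant split synthesizes the engagement-window
#: initiations plus five post-window sessions.
FULL_DEPLOYMENT_INITIATIONS: dict[str, int] = {
    "2ba4": 5, "50a8": 6, "996d": 3, "CFD1": 6, "5cd9": 2,
    "E5b2": 2, "03a7": 3, "2863": 9, "7d78": 4,
}

ENGAGEMENT_WINDOW_DAYS = 84
_DEPLOY_START = datetime(2026, 1, 5, 9, 0)


def _interleave(counts: dict[str, int]) -> list[str]:
    """Deterministic proportional interleave of status labels.

    Spreads each status uniformly over the prompt sequence so that the
    synthesized ledger's per-block completion matches the overall rate.
    """
    slots: list[tuple[float, int, str]] = []
    for j, (label, n) in enumerate(sorted(counts.items())):
        for k in range(n):
            slots.append(((k + 0.5) / n, j, label))
    slots.sort()
    return [label for _, _, label in slots]


def table2_ledger() -> PromptLedger:
    """The packaged completion-table fixture as a concrete ledger.

    Per participant and modality, ``scheduled`` instances are spread
    evenly across the 84-day window with statuses interleaved
    proportionally; completions happen 30 min after issue, and every
    device-failed prompt carries a failure event spanning its window.
    The result reproduces the transcribed table cell-for-cell under
    :func:`remowear.report.tabulate_completeness`.
    """
    led = PromptLedger()
    for pid, mods in COMPLETION_TABLE.items():
        led.deployments[pid] = _DEPLOY_START
        for mod, (sched, comp, inc_p, inc_d) in mods.items():
            assert sched == comp + inc_p + inc_d, (pid, mod)
            statuses = _interleave({"completed": comp, "expired": inc_p, "device_failed": inc_d})
            for i, status in enumerate(statuses):
                issued = _DEPLOY_START + timedelta(
                    days=(i + 0.5) * ENGAGEMENT_WINDOW_DAYS / sched
                )
                p = PromptInstance(
                    prompt_id=f"{pid}-{mod}-{i}",
                    participant_id=pid,
                    modality=mod,
                    issued_at=issued,
                    status=status,
                )
                if status == "completed":
                    p.completed_at = issued + timedelta(minutes=30)
                    if mod == "watch":
                        led.sessions.append((pid, p.completed_at))
                elif status == "device_failed":
                    led.failures.append(DeviceFailureEvent(pid, issued, p.expires_at))
                led.prompts.append(p)
    led.check_conservation()
    return led
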