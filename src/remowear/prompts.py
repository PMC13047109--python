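"""Symptom-triggered prompt scheduling, expiry, and cohort simulation.

The state machine mirrors a remote-monitoring protocol for older adults:

* a self-rated health (SRH) survey every 5–9 days on a rolling schedule,
  available for 48 h, with one reminder instance at +24 h if uncompleted;
* fair/poor SRH triggers a symptom survey (items graded 0–3) and a
  48-h watch monitoring prompt; good-or-better SRH triggers a watch
  prompt by random selection instead;
* a symptom response with any grade >= 2 opens a follow-up chain that
  re-prompts every 3 days until a response with all grades <= 1;
* a weekly smart-scale prompt, also 48-h availability with a reminder;
* uninitiated prompts expire at exactly +48 h (completion at the
  boundary counts), unless a confirmed device failure overlapped the
  prompt window, in which case the instance is attributed to the device.

Simulated time advances in whole minutes on a local clock without DST.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

SRH_LEVELS = ("excellent", "very good", "good", "fair", "poor")
MODALITIES = ("srh", "symptom", "scale", "watch")
EXPIRY = timedelta(hours=48)
REMINDER_AT = timedelta(hours=24)
FOLLOWUP = timedelta(days=3)
SCALE_PERIOD = timedelta(days=7)
SRH_GAP_DAYS = (5, 9)

PROVENANCES = ("scheduled", "reminder", "srh_triggered", "symptom_followup", "random_selection")


class ConfigError(ValueError):
    pass


class IntegrityError(ValueError):
    """Ledger conservation violated (scheduled != completed + expired + device_failed)."""


class AuditError(ValueError):
    """A completion was recorded after the prompt's expiry."""


@dataclass
class SurveyResponse:
    """A submitted SRH or symptom survey."""

    kind: str  # "srh" | "symptom"
    responded_at: datetime
    srh_level: str | None = None
    item_grades: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "srh":
            if self.srh_level not in SRH_LEVELS:
                raise ValueError(f"srh_level must be one of {SRH_LEVELS}")
        elif self.kind == "symptom":
            if self.item_grades is None or any(g not in (0, 1, 2, 3) for g in self.item_grades):
                raise ValueError("symptom item grades must each be in 0-3")
        else:
            raise ValueError(f"unknown response kind {self.kind!r}")

    @property
    def max_grade(self) -> int:
        return max(self.item_grades) if self.item_grades else 0


@dataclass
class PromptInstance:
    prompt_id: str
    participant_id: str
    modality: str
    issued_at: datetime
    provenance: str = "scheduled"
    status: str = "pending"  # -> completed | expired | device_failed
    completed_at: datetime | None = None

    @property
    def expires_at(self) -> datetime:
        return self.issued_at + EXPIRY


@dataclass
class DeviceFailureEvent:
    participant_id: str
    start: datetime
    end: datetime

    def overlaps(self, a: datetime, b: datetime) -> bool:
        return self.start <= b and self.end >= a


@dataclass
class ParticipantState:
    """Mutable scheduling state for one participant."""

    participant_id: str
    deployment_start: datetime
    next_srh_due: datetime | None = None
    last_srh_level: str | None = None
    chain_open: bool = False
    chain_next_due: datetime | None = None
    srh_level_idx: int = 2  # "good"


@dataclass
class PromptLedger:
    """Every generated prompt instance plus failures, responses, sessions."""

    prompts: list[PromptInstance] = field(default_factory=list)
    failures: list[DeviceFailureEvent] = field(default_factory=list)
    responses: list[SurveyResponse] = field(default_factory=list)
    deployments: dict[str, datetime] = field(default_factory=dict)
    #: watch session initiations: (participant_id, initiated_at)
    sessions: list[tuple[str, datetime]] = field(default_factory=list)

    LEDGER_COLUMNS = (
        "participant_id", "prompt_id", "modality", "provenance",
        "issued_at", "expires_at", "status", "completed_at",
    )

    def to_frame(self) -> pd.DataFrame:
        if not self.prompts:
            return pd.DataFrame(columns=list(self.LEDGER_COLUMNS))
        return pd.DataFrame(
            [
                {
                    "participant_id": p.participant_id,
                    "prompt_id": p.prompt_id,
                    "modality": p.modality,
                    "provenance": p.provenance,
                    "issued_at": p.issued_at.isoformat(),
                    "expires_at": p.expires_at.isoformat(),
                    "status": p.status,
                    "completed_at": p.completed_at.isoformat() if p.completed_at else "",
                }
                for p in self.prompts
            ]
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, deployments: dict[str, datetime] | None = None) -> "PromptLedger":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        led = cls(deployments=deployments or {})
        for _, r in df.iterrows():
            led.prompts.append(
                PromptInstance(
                    prompt_id=r["prompt_id"],
                    participant_id=r["participant_id"],
                    modality=r["modality"],
                    issued_at=datetime.fromisoformat(r["issued_at"]),
                    provenance=r["provenance"],
                    status=r["status"],
                    completed_at=datetime.fromisoformat(r["completed_at"]) if r["completed_at"] else None,
                )
            )
        for pid in sorted({p.participant_id for p in led.prompts}):
            led.deployments.setdefault(
                pid, min(p.issued_at for p in led.prompts if p.participant_id == pid)
            )
        return led

    def check_conservation(self) -> None:
        """Assert scheduled = completed + expired + device_failed per participant × modality."""
        df = self.to_frame()
        if df.empty:
            return
        for (pid, mod), grp in df.groupby(["participant_id", "modality"]):
            terminal = grp["status"].isin(["completed", "expired", "device_failed"]).sum()
            if terminal != len(grp):
                raise IntegrityError(
                    f"participant {pid} modality {mod}: "
                    f"{len(grp) - terminal} prompt(s) not resolved"
                )


# ---------------------------------------------------------------------------
# scheduling operations


def schedule_srh(
    state: ParticipantState, horizon_days: int, rng: np.random.Generator
) -> list[PromptInstance]:
    """Primary SRH prompts at rolling 5–9 day gaps over the horizon.

    The first prompt is issued at deployment start; successive gaps are
    integer days drawn uniformly from {5, ..., 9}.  Reminder instances
    are emitted separately once completion behavior is known.
    """
    out: list[PromptInstance] = []
    t = state.deployment_start
    end = state.deployment_start + timedelta(days=horizon_days)
    k = 0
    while t < end:
        out.append(
            PromptInstance(
                prompt_id=f"{state.participant_id}-srh-{k}",
                participant_id=state.participant_id,
                modality="srh",
                issued_at=t,
            )
        )
        k += 1
        t = t + timedelta(days=int(rng.integers(SRH_GAP_DAYS[0], SRH_GAP_DAYS[1] + 1)))
    state.next_srh_due = t
    return out


def schedule_scale(state: ParticipantState, horizon_days: int) -> list[PromptInstance]:
    """Weekly scale prompts from deployment start, each with 48-h availability."""
    out = []
    t = state.deployment_start
    end = state.deployment_start + timedelta(days=horizon_days)
    k = 0
    while t < end:
        out.append(
            PromptInstance(
                prompt_id=f"{state.participant_id}-scale-{k}",
                participant_id=state.participant_id,
                modality="scale",
                issued_at=t,
            )
        )
        k += 1
        t += SCALE_PERIOD
    return out


def process_srh_response(
    state: ParticipantState,
    response: SurveyResponse,
    p_random_watch: float,
    rng: np.random.Generator,
    seq: int = 0,
) -> list[PromptInstance]:
    """Trigger logic for a completed SRH survey.

    fair/poor -> symptom survey (unless a follow-up chain is already
    open) plus a watch prompt, both provenance ``srh_triggered``;
    good-or-better -> watch prompt with probability ``p_random_watch``
    (provenance ``random_selection``).
    """
    if response.kind != "srh":
        raise TypeError("process_srh_response requires an SRH response")
    state.last_srh_level = response.srh_level
    pid = state.participant_id
    t = response.responded_at
    out: list[PromptInstance] = []
    if response.srh_level in ("fair", "poor"):
        if not state.chain_open:
            out.append(
                PromptInstance(
                    prompt_id=f"{pid}-sym-t{seq}",
                    participant_id=pid,
                    modality="symptom",
                    issued_at=t,
                    provenance="srh_triggered",
                )
            )
        out.append(
            PromptInstance(
                prompt_id=f"{pid}-watch-t{seq}",
                participant_id=pid,
                modality="watch",
                issued_at=t,
                provenance="srh_triggered",
            )
        )
    else:
        if rng.random() < p_random_watch:
            out.append(
                PromptInstance(
                    prompt_id=f"{pid}-watch-r{seq}",
                    participant_id=pid,
                    modality="watch",
                    issued_at=t,
                    provenance="random_selection",
                )
            )
    return out


def process_symptom_response(
    state: ParticipantState, response: SurveyResponse, seq: int = 0
) -> PromptInstance | None:
    """Open/continue/close the follow-up chain from a symptom response.

    Max grade >= 2 schedules the next symptom prompt at +3 days (chain
    open); all grades <= 1 closes the chain and schedules nothing.
    """
    if response.kind != "symptom":
        raise TypeError("process_symptom_response requires a symptom response")
    if response.max_grade >= 2:
        state.chain_open = True
        state.chain_next_due = response.responded_at + FOLLOWUP
        return PromptInstance(
            prompt_id=f"{state.participant_id}-sym-f{seq}",
            participant_id=state.participant_id,
            modality="symptom",
            issued_at=state.chain_next_due,
            provenance="symptom_followup",
        )
    state.chain_open = False
    state.chain_next_due = None
    return None


def expire_and_resolve(
    ledger: PromptLedger, now: datetime, device_failures: list[DeviceFailureEvent] | None = None
) -> PromptLedger:
    """Resolve pending prompts past expiry to expired / device_failed.

    Completion at exactly +48 h counts as completed (inclusive
    boundary); a pending prompt whose window overlaps a logged device
    failure resolves to ``device_failed``.
    """
    failures = list(ledger.failures) + list(device_failures or [])
    for p in ledger.prompts:
        if p.status == "completed" and p.completed_at is not None:
            if p.completed_at > p.expires_at:
                raise AuditError(
                    f"{p.prompt_id}: completion at {p.completed_at} after expiry {p.expires_at}"
                )
        if p.status == "pending" and now >= p.expires_at:
            hit = any(
                f.participant_id == p.participant_id and f.overlaps(p.issued_at, p.expires_at)
                for f in failures
            )
            p.status = "device_failed" if hit else "expired"
    for f in device_failures or []:
        ledger.failures.append(f)
    return ledger


def record_completion(prompt: PromptInstance, when: datetime) -> None:
    """Mark a prompt completed; completion after expiry is rejected."""
    if when > prompt.expires_at:
        raise AuditError(f"{prompt.prompt_id}: completion at {when} after expiry")
    prompt.status = "completed"
    prompt.completed_at = when


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class ParticipantBehavior:
    """Behavior model for one simulated participant.

    Completion probabilities are per prompt instance by modality;
    ``device_failure_rate`` is per prompt instance by modality (a drawn
    failure logs an event spanning the prompt window).  SRH levels
    follow an ordinal random walk over the five levels with a downdrift
    (probability mass shifted toward worse health each response).
    """

    participant_id: str
    p_complete: dict = field(
        default_factory=lambda: {"srh": 0.86, "symptom": 0.87, "scale": 0.83, "watch": 0.74}
    )
    device_failure_rate: dict = field(
        default_factory=lambda: {"srh": 0.0, "symptom": 0.0, "scale": 0.0, "watch": 0.13}
    )
    srh_start_idx: int = 2
    srh_downdrift: float = 0.03
    p_symptom_severe: float = 0.5  # initial symptom survey has a grade >= 2
    p_symptom_resolve: float = 0.5  # chance a follow-up response resolves (all grades <= 1)
    n_symptom_items: int = 5

    def validate(self) -> None:
        for d in (self.p_complete, self.device_failure_rate):
            for mod, p in d.items():
                if mod not in MODALITIES or not (0.0 <= p <= 1.0):
                    raise ConfigError(f"invalid probability {p} for modality {mod!r}")
        for p in (self.srh_downdrift, self.p_symptom_severe, self.p_symptom_resolve):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p} out of [0,1]")


def _substream(seed: int, participant_index: int, purpose: int) -> np.random.Generator:
    """Named RNG substream: one per participant per purpose, from one run seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, participant_index, purpose)))


def _draw_grades(
    rng: np.random.Generator, n_items: int, severe: bool
) -> tuple[int, ...]:
    """Item grades 0–3 with at least one grade >= 2 iff ``severe``."""
    if severe:
        grades = rng.integers(0, 4, size=n_items)
        if grades.max() < 2:
            grades[int(rng.integers(0, n_items))] = int(rng.integers(2, 4))
    else:
        grades = rng.integers(0, 2, size=n_items)
    return tuple(int(g) for g in grades)


def _walk_srh(rng: np.random.Generator, idx: int, downdrift: float) -> int:
    """One ordinal random-walk step over SRH levels (4 = poor is worst)."""
    base = (1 - downdrift) / 3.0
    move = rng.choice([-1, 0, 1], p=[base, base, base + downdrift])
    return int(np.clip(idx + move, 0, len(SRH_LEVELS) - 1))


def simulate_participant(
    behavior: ParticipantBehavior,
    seed: int,
    participant_index: int,
    horizon_days: int,
    deployment_start: datetime,
    p_random_watch: float = 0.5,
    scale_reminders: bool = True,
    ledger: PromptLedger | None = None,
) -> PromptLedger:
    """Discrete-event simulation of one participant's prompt stream."""
    behavior.validate()
    rng_sched = _substream(seed, participant_index, 0)
    rng_select = _substream(seed, participant_index, 1)
    rng_behav = _substream(seed, participant_index, 2)

    led = ledger if ledger is not None else PromptLedger()
    pid = behavior.participant_id
    led.deployments[pid] = deployment_start
    state = ParticipantState(
        participant_id=pid,
        deployment_start=deployment_start,
        srh_level_idx=behavior.srh_start_idx,
    )
    end = deployment_start + timedelta(days=horizon_days)

    queue: list[tuple[datetime, int, PromptInstance]] = []
    seq = 0

    def push(p: PromptInstance) -> None:
        nonlocal seq
        if p.issued_at < end:
            heapq.heappush(queue, (p.issued_at, seq, p))
            seq += 1

    for p in schedule_srh(state, horizon_days, rng_sched):
        push(p)
    for p in schedule_scale(state, horizon_days):
        push(p)

    trig_seq = 0
    while queue:
        _, _, p = heapq.heappop(queue)
        led.prompts.append(p)

        # outcome draws, minute resolution
        fail_rate = behavior.device_failure_rate.get(p.modality, 0.0)
        p_done = behavior.p_complete.get(p.modality, 0.0)
        if rng_behav.random() < fail_rate:
            p.status = "device_failed"
            led.failures.append(DeviceFailureEvent(pid, p.issued_at, p.expires_at))
        elif rng_behav.random() < p_done:
            # most responses arrive within hours of the prompt
            delay_min = min(int(rng_behav.exponential(360.0)), int(EXPIRY.total_seconds() // 60))
            record_completion(p, p.issued_at + timedelta(minutes=delay_min))
        else:
            p.status = "expired"

        # one reminder for uncompleted primary SRH / scale prompts at +24 h
        wants_reminder = p.modality == "srh" or (p.modality == "scale" and scale_reminders)
        if wants_reminder and p.provenance in ("scheduled",):
            uncompleted_at_24h = p.status != "completed" or (
                p.completed_at is not None and p.completed_at > p.issued_at + REMINDER_AT
            )
            if uncompleted_at_24h:
                push(
                    PromptInstance(
                        prompt_id=p.prompt_id + "-rem",
                        participant_id=pid,
                        modality=p.modality,
                        issued_at=p.issued_at + REMINDER_AT,
                        provenance="reminder",
                    )
                )

        if p.status != "completed":
            # an expired open-chain follow-up keeps the chain sampling
            if p.modality == "symptom" and p.provenance == "symptom_followup" and state.chain_open:
                push(
                    PromptInstance(
                        prompt_id=f"{pid}-sym-f{trig_seq}",
                        participant_id=pid,
                        modality="symptom",
                        issued_at=p.issued_at + FOLLOWUP,
                        provenance="symptom_followup",
                    )
                )
                trig_seq += 1
            continue

        if p.modality == "srh":
            state.srh_level_idx = _walk_srh(rng_behav, state.srh_level_idx, behavior.srh_downdrift)
            resp = SurveyResponse(
                kind="srh", responded_at=p.completed_at, srh_level=SRH_LEVELS[state.srh_level_idx]
            )
            led.responses.append(resp)
            for trig in process_srh_response(state, resp, p_random_watch, rng_select, seq=trig_seq):
                trig_seq += 1
                push(trig)
        elif p.modality == "symptom":
            if p.provenance == "symptom_followup":
                severe = rng_behav.random() >= behavior.p_symptom_resolve
            else:
                severe = rng_behav.random() < behavior.p_symptom_severe
            resp = SurveyResponse(
                kind="symptom",
                responded_at=p.completed_at,
                item_grades=_draw_grades(rng_behav, behavior.n_symptom_items, severe),
            )
            led.responses.append(resp)
            nxt = process_symptom_response(state, resp, seq=trig_seq)
            if nxt is not None:
                trig_seq += 1
                push(nxt)
        elif p.modality == "watch":
            led.sessions.append((pid, p.completed_at))

    expire_and_resolve(led, now=end + EXPIRY)
    return led


def run_simulation(
    cohort: list[ParticipantBehavior],
    seed: int,
    horizon_days: int = 84,
    deployment_start: datetime = datetime(2026, 1, 5, 9, 0),
    p_random_watch: float = 0.5,
    scale_reminders: bool = True,
) -> PromptLedger:
    """Simulate a cohort; deterministic given (cohort, seed).

    The returned ledger satisfies conservation (every instance resolved
    to completed / expired / device_failed) and carries watch-session
    initiation records consumable by the accelerometry metrics stage.
    """
    if not (0.0 <= p_random_watch <= 1.0):
        raise ConfigError("p_random_watch must lie in [0, 1]")
    led = PromptLedger()
    for i, behavior in enumerate(cohort):
        simulate_participant(
            behavior,
            seed=seed,
            participant_index=i,
            horizon_days=horizon_days,
            deployment_start=deployment_start,
            p_random_watch=p_random_watch,
            scale_reminders=scale_reminders,
            ledger=led,
        )
    led.check_conservation()
    return led
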