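"""Round-based ED session simulator driven by bot-player policies.

A session runs a fixed number of discrete rounds (default 12 rounds of 30
simulated minutes). Each round applies, in fixed order:

    arrivals -> triage decisions -> staff allocation -> activity ticks
             -> completions/discharges -> scoring updates

Roles are ``triage`` plus ``module_1`` .. ``module_n``; exactly one module
is red and every urgent patient is hard-routed there regardless of what the
triage policy asked for (the override is logged as a ``rule_enforcement``
event). The engine emits a causally ordered telemetry log of
:class:`GameEvent` records; the scoring module recomputes the token ledger
from the same log independently of the ``scoring_update`` events written
here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._rng import substream
from .profile_deck import ArrivalSchedule, PatientProfile
from .scoring import (
    LedgerEntry,
    ScoringRules,
    TokenLedger,
    score_activity_execution,
    score_resilience,
    score_resource_management,
    score_throughput,
)

__all__ = [
    "SessionConfig",
    "TriagePolicy",
    "ModulePolicy",
    "PolicySet",
    "GameEvent",
    "SessionResult",
    "run_session",
    "write_event_log",
    "read_event_log",
    "EngineError",
]

EVENT_TYPES = frozenset(
    {
        "session_start",
        "round_start",
        "arrival",
        "triage_refer_out",
        "triage_admit",
        "triage_wait",
        "triage_unstaffed",
        "assign_module",
        "rule_enforcement",
        "allocate_staff",
        "edit_profile",
        "broadcast_invite",
        "activity_tick",
        "activity_complete",
        "discharge",
        "resilience_state",
        "scoring_update",
        "session_end",
    }
)


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class GameEvent:
    """One telemetry record: round, acting role, event type, payload."""

    round: int
    actor_role: str
    event_type: str
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "round": self.round,
                "actor_role": self.actor_role,
                "event_type": self.event_type,
                "payload": self.payload,
            },
            sort_keys=True,
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, line: str) -> "GameEvent":
        d = json.loads(line)
        return cls(
            round=int(d["round"]),
            actor_role=str(d["actor_role"]),
            event_type=str(d["event_type"]),
            payload=dict(d["payload"]),
        )


@dataclass(frozen=True)
class TriagePolicy:
    """Stochastic triage heuristic: refer out with fixed probability,
    otherwise admit to the least-loaded non-full module (urgent patients are
    routed to the red module by the engine regardless)."""

    refer_probability: float = 0.15
    prefer_module: int | None = None  # deliberately faulty policies for testing


@dataclass(frozen=True)
class ModulePolicy:
    """Stochastic module heuristic.

    ``neglect_probability`` is the per-activity-per-round chance the bot
    forgets to allocate staff (generating under-staffing penalties and
    delays); edit/invite propensities produce content-generation telemetry.
    """

    neglect_probability: float = 0.02
    edit_profile_probability: float = 0.30
    invite_probability: float = 0.15


@dataclass(frozen=True)
class PolicySet:
    triage: TriagePolicy = field(default_factory=TriagePolicy)
    module: ModulePolicy = field(default_factory=ModulePolicy)


@dataclass(frozen=True)
class SessionConfig:
    """Session parameters; defaults model a 12-round, 6-hour shift with
    five modules (module_1 red) and one triage nurse."""

    rounds: int = 12
    minutes_per_round: int = 30
    n_modules: int = 5
    red_module: int = 1
    module_capacity: int = 4
    doctors_per_module: int = 3
    nurses_per_module: int = 6
    triage_nurses: int = 1
    seed: int = 0
    rules: ScoringRules = field(default_factory=ScoringRules)

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise EngineError("rounds must be >= 1")
        if self.n_modules < 1:
            raise EngineError("n_modules must be >= 1")
        if not 1 <= self.red_module <= self.n_modules:
            raise EngineError("red_module must name one of the modules")
        if self.minutes_per_round < 1:
            raise EngineError("minutes_per_round must be >= 1")

    @property
    def simulated_minutes(self) -> int:
        return self.rounds * self.minutes_per_round

    def module_roles(self) -> list[str]:
        return [f"module_{k}" for k in range(1, self.n_modules + 1)]

    @property
    def red_role(self) -> str:
        return f"module_{self.red_module}"


@dataclass
class _ActivityProgress:
    index: int = 0  # which activity in the plan
    progress: int = 0  # completed rounds of the current activity
    elapsed: int = 0  # rounds the current activity has been active


@dataclass
class _AdmittedPatient:
    profile: PatientProfile
    state: _ActivityProgress = field(default_factory=_ActivityProgress)

    @property
    def current_activity(self):
        return self.profile.activities[self.state.index]

    @property
    def done(self) -> bool:
        return self.state.index >= len(self.profile.activities)


@dataclass
class SessionResult:
    """Final session state plus conservation counters."""

    events: list[GameEvent]
    ledger: TokenLedger
    arrivals: int
    referred_out: int
    discharged: int
    remaining: int

    def conserved(self) -> bool:
        return self.arrivals == self.referred_out + self.discharged + self.remaining


def run_session(
    config: SessionConfig,
    deck: Sequence[PatientProfile],
    schedule: ArrivalSchedule,
    policies: PolicySet | None = None,
) -> SessionResult:
    """Execute a full session and return the ordered event log.

    Deterministic: identical ``(config, deck, schedule, policies)`` including
    ``config.seed`` produce an identical log.
    """
    if schedule.rounds > config.rounds:
        raise EngineError("schedule covers more rounds than the session")
    policies = policies or PolicySet()
    rules = config.rules
    by_id = {p.profile_id: p for p in deck}
    for batch in schedule.arrivals:
        for pid in batch:
            if pid not in by_id:
                raise EngineError(f"schedule references unknown profile {pid}")

    rng_triage = substream(config.seed, "engine", "triage")
    rng_module = substream(config.seed, "engine", "module")

    events: list[GameEvent] = []
    ledger = TokenLedger()
    modules: dict[str, list[_AdmittedPatient]] = {r: [] for r in config.module_roles()}
    triage_queue: list[PatientProfile] = []
    n_arrivals = n_referred = n_discharged = 0
    rejections = 0

    def emit(event: GameEvent) -> None:
        events.append(event)

    def pend_score(pending: list, round_no: int, role: str, indicator: str, delta: int, cause: int) -> None:
        pending.append((round_no, role, indicator, delta, cause))

    emit(
        GameEvent(
            0,
            "system",
            "session_start",
            {
                "rounds": config.rounds,
                "minutes_per_round": config.minutes_per_round,
                "n_modules": config.n_modules,
                "red_role": config.red_role,
                "module_roles": config.module_roles(),
                "seed": config.seed,
            },
        )
    )

    for round_no in range(1, config.rounds + 1):
        emit(GameEvent(round_no, "system", "round_start", {"minute": (round_no - 1) * config.minutes_per_round}))
        pending: list[tuple[int, str, str, int, int]] = []

        # --- arrivals -----------------------------------------------------
        if round_no <= schedule.rounds:
            for pid in schedule.for_round(round_no):
                triage_queue.append(by_id[pid])
                n_arrivals += 1
                emit(GameEvent(round_no, "triage", "arrival", {"profile_id": pid, "urgent": by_id[pid].urgent}))

        # --- triage decisions --------------------------------------------
        if config.triage_nurses == 0:
            emit(GameEvent(round_no, "triage", "triage_unstaffed", {}))
            pend_score(pending, round_no, "triage", "RM",
                       score_resource_management("triage", rules), len(events) - 1)
        else:
            still_waiting: list[PatientProfile] = []
            for patient in triage_queue:
                target, overridden = _triage_decide(patient, config, modules, policies.triage, rng_triage)
                if overridden:
                    emit(
                        GameEvent(
                            round_no,
                            "triage",
                            "rule_enforcement",
                            {"profile_id": patient.profile_id, "forced_module": config.red_role},
                        )
                    )
                if target == "refer":
                    n_referred += 1
                    rejections += 1
                    emit(GameEvent(round_no, "triage", "triage_refer_out", {"profile_id": patient.profile_id}))
                    if rejections % rules.rejections_per_penalty == 0:
                        pend_score(pending, round_no, "triage", "PT", -1, len(events) - 1)
                elif target is None:
                    emit(GameEvent(round_no, "triage", "triage_wait", {"profile_id": patient.profile_id}))
                    still_waiting.append(patient)
                else:
                    emit(GameEvent(round_no, "triage", "triage_admit", {"profile_id": patient.profile_id}))
                    emit(
                        GameEvent(
                            round_no,
                            "triage",
                            "assign_module",
                            {"profile_id": patient.profile_id, "module_role": target, "urgent": patient.urgent},
                        )
                    )
                    modules[target].append(_AdmittedPatient(patient))
            triage_queue = still_waiting

        # --- staff allocation --------------------------------------------
        allocated: dict[str, dict[str, set[str]]] = {}  # role -> pid -> staffed?
        assigned_doctors: dict[str, int] = {}
        for role in config.module_roles():
            free_d, free_n = config.doctors_per_module, config.nurses_per_module
            staffed: dict[str, set[str]] = {"ok": set()}
            for ap in modules[role]:
                act = ap.current_activity
                if rng_module.random() < policies.module.neglect_probability:
                    continue  # bot forgot this activity this round
                if free_d >= act.required_doctors and free_n >= act.required_nurses:
                    free_d -= act.required_doctors
                    free_n -= act.required_nurses
                    staffed["ok"].add(ap.profile.profile_id)
                    emit(
                        GameEvent(
                            round_no,
                            role,
                            "allocate_staff",
                            {
                                "profile_id": ap.profile.profile_id,
                                "activity_id": act.activity_id,
                                "doctors": act.required_doctors,
                                "nurses": act.required_nurses,
                            },
                        )
                    )
            allocated[role] = staffed
            assigned_doctors[role] = config.doctors_per_module - free_d

            if modules[role]:
                if rng_module.random() < policies.module.edit_profile_probability:
                    pid = modules[role][0].profile.profile_id
                    emit(GameEvent(round_no, role, "edit_profile", {"profile_id": pid}))
                if rng_module.random() < policies.module.invite_probability:
                    emit(GameEvent(round_no, role, "broadcast_invite", {}))

        # --- activity ticks, completions, discharges ---------------------
        for role in config.module_roles():
            remaining: list[_AdmittedPatient] = []
            for ap in modules[role]:
                act = ap.current_activity
                ap.state.elapsed += 1
                staffed = ap.profile.profile_id in allocated[role]["ok"]
                if staffed:
                    ap.state.progress += 1
                    emit(
                        GameEvent(
                            round_no,
                            role,
                            "activity_tick",
                            {
                                "profile_id": ap.profile.profile_id,
                                "activity_id": act.activity_id,
                                "stalled": False,
                                "progress": ap.state.progress,
                            },
                        )
                    )
                else:
                    emit(
                        GameEvent(
                            round_no,
                            role,
                            "activity_tick",
                            {
                                "profile_id": ap.profile.profile_id,
                                "activity_id": act.activity_id,
                                "stalled": True,
                                "module_role": role,
                                "progress": ap.state.progress,
                            },
                        )
                    )
                    kind = "red" if role == config.red_role else "normal"
                    pend_score(pending, round_no, role, "RM",
                               score_resource_management(kind, rules), len(events) - 1)

                if ap.state.progress >= act.planned_rounds:
                    emit(
                        GameEvent(
                            round_no,
                            role,
                            "activity_complete",
                            {
                                "profile_id": ap.profile.profile_id,
                                "activity_id": act.activity_id,
                                "module_role": role,
                                "planned_rounds": act.planned_rounds,
                                "actual_rounds": ap.state.elapsed,
                            },
                        )
                    )
                    kind = "red" if role == config.red_role else "normal"
                    ae = score_activity_execution(act.planned_rounds, ap.state.elapsed, kind, rules)
                    if ae:
                        pend_score(pending, round_no, role, "AE", ae, len(events) - 1)
                    ap.state = _ActivityProgress(index=ap.state.index + 1)
                if ap.done:
                    n_discharged += 1
                    emit(
                        GameEvent(
                            round_no,
                            role,
                            "discharge",
                            {"profile_id": ap.profile.profile_id, "module_role": role},
                        )
                    )
                    cause = len(events) - 1
                    mod_delta, triage_delta = score_throughput(role == config.red_role, rules)
                    pend_score(pending, round_no, role, "PT", mod_delta, cause)
                    if triage_delta:
                        pend_score(pending, round_no, "triage", "PT", triage_delta, cause)
                else:
                    remaining.append(ap)
            modules[role] = remaining

        # --- round-end resilience snapshot -------------------------------
        for role in config.module_roles():
            free_doctors = config.doctors_per_module - assigned_doctors[role]
            emit(
                GameEvent(
                    round_no,
                    role,
                    "resilience_state",
                    {"module_role": role, "free_doctors": free_doctors},
                )
            )
            kind = "red" if role == config.red_role else "normal"
            pr = score_resilience(kind, free_doctors, rules)
            if pr:
                pend_score(pending, round_no, role, "PR", pr, len(events) - 1)

        # --- scoring updates (last sub-phase of the round) ----------------
        for rnd, role, indicator, delta, cause in pending:
            ledger.append(LedgerEntry(rnd, role, indicator, delta, cause))
            emit(
                GameEvent(
                    rnd,
                    role,
                    "scoring_update",
                    {"indicator": indicator, "delta": delta, "cause": cause},
                )
            )

    remaining_total = len(triage_queue) + sum(len(q) for q in modules.values())
    emit(
        GameEvent(
            config.rounds,
            "system",
            "session_end",
            {
                "arrivals": n_arrivals,
                "referred_out": n_referred,
                "discharged": n_discharged,
                "remaining": remaining_total,
            },
        )
    )
    return SessionResult(
        events=events,
        ledger=ledger,
        arrivals=n_arrivals,
        referred_out=n_referred,
        discharged=n_discharged,
        remaining=remaining_total,
    )


def _triage_decide(
    patient: PatientProfile,
    config: SessionConfig,
    modules: dict[str, list],
    policy: TriagePolicy,
    rng,
) -> tuple[str | None, bool]:
    """Return ``(decision, overridden)`` where decision is a module role,
    ``"refer"``, or ``None`` (wait at triage)."""
    draw = rng.random()  # drawn for every patient to keep streams aligned
    if patient.urgent:
        red = config.red_role
        # a faulty policy asking for a non-red module is overridden and logged
        overridden = policy.prefer_module is not None and f"module_{policy.prefer_module}" != red
        if len(modules[red]) >= config.module_capacity:
            return None, overridden
        return red, overridden
    if draw < policy.refer_probability:
        return "refer", False
    if policy.prefer_module is not None:
        role = f"module_{policy.prefer_module}"
        return (role if len(modules[role]) < config.module_capacity else None), False
    open_modules = [
        r for r in config.module_roles()
        if r != config.red_role and len(modules[r]) < config.module_capacity
    ]
    if not open_modules:  # normal patients may overflow into red if it is open
        red = config.red_role
        return (red if len(modules[red]) < config.module_capacity else None), False
    open_modules.sort(key=lambda r: (len(modules[r]), r))
    return open_modules[0], False


def write_event_log(events: Iterable[GameEvent], path: str | Path) -> None:
    """Write events as JSON Lines, one event per line."""
    with Path(path).open("w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_event_log(path: str | Path) -> list[GameEvent]:
    events = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                ev = GameEvent.from_json(line)
            except (json.JSONDecodeError, KeyError) as exc:
                raise EngineError(f"{path}: malformed event at line {lineno}: {exc}") from exc
            if ev.event_type not in EVENT_TYPES:
                raise EngineError(f"{path}: unknown event_type {ev.event_type!r} at line {lineno}")
            events.append(ev)
    return events
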