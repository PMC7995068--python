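"""Synthetic patient-profile deck and per-round arrival schedule.

The deck stands in for the patient-flow data of a large pediatric emergency
department: each card carries an urgency flag (the only priority level that
matters downstream — urgent cards must be routed to the red module), a
cosmetic priority class, and an ordered plan of activities with staff
requirements and planned durations in rounds.

Default case mix (all parameters are configurable, none is a measured fact):
activity count per patient ~ 1 + Binomial(3, 0.5); planned duration per
activity in {1, 2, 3} rounds with weights {0.5, 0.3, 0.2}; staff requirement
per activity drawn so that at least one of doctor/nurse is required.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import substream

__all__ = [
    "ActivityRequirement",
    "PatientProfile",
    "ArrivalSchedule",
    "CaseMix",
    "generate_deck",
    "generate_arrivals",
    "read_deck",
    "write_deck",
    "read_schedule",
    "write_schedule",
    "DeckError",
]


class DeckError(ValueError):
    """Raised for invalid deck parameters or malformed deck files."""


@dataclass(frozen=True)
class ActivityRequirement:
    """One planned care activity on a patient card."""

    activity_id: str
    planned_rounds: int
    required_doctors: int
    required_nurses: int

    def __post_init__(self) -> None:
        if self.planned_rounds < 1:
            raise DeckError(f"planned_rounds must be >= 1, got {self.planned_rounds}")
        if self.required_doctors < 0 or self.required_nurses < 0:
            raise DeckError("staff requirements must be non-negative")
        if self.required_doctors + self.required_nurses < 1:
            raise DeckError("each activity needs at least one staff member")


@dataclass(frozen=True)
class PatientProfile:
    """One game card: urgency, cosmetic priority, and an activity plan."""

    profile_id: str
    urgent: bool
    priority_class: int
    activities: tuple[ActivityRequirement, ...]
    sbar_note: str = ""

    def __post_init__(self) -> None:
        if not self.activities:
            raise DeckError(f"profile {self.profile_id} has no activities")


@dataclass(frozen=True)
class ArrivalSchedule:
    """Per-round arrivals at triage; each profile arrives at most once."""

    rounds: int
    arrivals: tuple[tuple[str, ...], ...]  # arrivals[r-1] = profile ids in round r

    def __post_init__(self) -> None:
        if len(self.arrivals) != self.rounds:
            raise DeckError("arrival list length must equal number of rounds")
        seen: set[str] = set()
        for batch in self.arrivals:
            for pid in batch:
                if pid in seen:
                    raise DeckError(f"profile {pid} scheduled more than once")
                seen.add(pid)

    @property
    def total(self) -> int:
        return sum(len(b) for b in self.arrivals)

    def for_round(self, round_no: int) -> tuple[str, ...]:
        return self.arrivals[round_no - 1]


@dataclass(frozen=True)
class CaseMix:
    """Parametric case-mix distribution for deck generation."""

    extra_activities_n: int = 3
    extra_activities_p: float = 0.5
    duration_choices: tuple[int, ...] = (1, 2, 3)
    duration_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    doctor_probability: float = 0.5
    max_nurses: int = 2
    priority_classes: tuple[int, ...] = (1, 2, 3, 4, 5)


def _validate_deck(profiles: Sequence[PatientProfile]) -> tuple[PatientProfile, ...]:
    ids = [p.profile_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DeckError(f"duplicate profile_id(s): {dupes}")
    return tuple(profiles)


def generate_deck(
    size: int = 90,
    urgent_fraction: float = 0.15,
    seed: int = 0,
    case_mix: CaseMix | None = None,
) -> tuple[PatientProfile, ...]:
    """Generate ``size`` unique patient profiles.

    Urgency flags are i.i.d. Bernoulli(``urgent_fraction``); activity plans
    are sampled from ``case_mix``. The result is a pure function of the
    arguments (identical inputs give a bit-identical deck).
    """
    if size < 1:
        raise DeckError(f"deck size must be >= 1, got {size}")
    if not 0.0 <= urgent_fraction <= 1.0:
        raise DeckError(f"urgent_fraction must be in [0, 1], got {urgent_fraction}")
    mix = case_mix or CaseMix()
    rng = substream(seed, "deck")
    weights = np.asarray(mix.duration_weights, dtype=float)
    weights = weights / weights.sum()

    profiles: list[PatientProfile] = []
    width = max(3, len(str(size)))
    for i in range(size):
        pid = f"P{i + 1:0{width}d}"
        urgent = bool(rng.random() < urgent_fraction)
        n_act = 1 + int(rng.binomial(mix.extra_activities_n, mix.extra_activities_p))
        acts = []
        for j in range(n_act):
            planned = int(rng.choice(mix.duration_choices, p=weights))
            doctors = int(rng.random() < mix.doctor_probability)
            nurses = int(rng.integers(0, mix.max_nurses + 1))
            if doctors + nurses == 0:
                nurses = 1
            acts.append(
                ActivityRequirement(
                    activity_id=f"{pid}-A{j + 1}",
                    planned_rounds=planned,
                    required_doctors=doctors,
                    required_nurses=nurses,
                )
            )
        priority = 1 if urgent else int(rng.choice(mix.priority_classes[1:]))
        profiles.append(
            PatientProfile(
                profile_id=pid,
                urgent=urgent,
                priority_class=priority,
                activities=tuple(acts),
                sbar_note=f"SBAR note for {pid}",
            )
        )
    return _validate_deck(profiles)


def generate_arrivals(
    deck: Sequence[PatientProfile],
    rounds: int,
    mean_per_round: float,
    seed: int = 0,
) -> ArrivalSchedule:
    """Draw a per-round arrival schedule without replacement from the deck.

    Round counts are Poisson(``mean_per_round``) truncated so the schedule
    never references more profiles than the deck holds; hitting that bound
    emits a warning.
    """
    if not deck:
        raise DeckError("deck must be non-empty")
    if rounds < 1:
        raise DeckError(f"rounds must be >= 1, got {rounds}")
    if mean_per_round < 0:
        raise DeckError(f"mean_per_round must be >= 0, got {mean_per_round}")
    rng = substream(seed, "arrivals")
    order = list(rng.permutation([p.profile_id for p in deck]))
    batches: list[tuple[str, ...]] = []
    cursor = 0
    truncated = False
    for _ in range(rounds):
        want = int(rng.poisson(mean_per_round))
        take = min(want, len(order) - cursor)
        if take < want:
            truncated = True
        batches.append(tuple(order[cursor : cursor + take]))
        cursor += take
    if truncated:
        warnings.warn(
            "requested arrival volume exceeded deck size; schedule truncated",
            stacklevel=2,
        )
    return ArrivalSchedule(rounds=rounds, arrivals=tuple(batches))


# ---------------------------------------------------------------------------
# serialization


def _profile_to_dict(p: PatientProfile) -> dict:
    return {
        "profile_id": p.profile_id,
        "urgent": p.urgent,
        "priority_class": p.priority_class,
        "sbar_note": p.sbar_note,
        "activities": [
            {
                "activity_id": a.activity_id,
                "planned_rounds": a.planned_rounds,
                "required_doctors": a.required_doctors,
                "required_nurses": a.required_nurses,
            }
            for a in p.activities
        ],
    }


def _profile_from_dict(d: dict, where: str) -> PatientProfile:
    try:
        return PatientProfile(
            profile_id=str(d["profile_id"]),
            urgent=bool(d["urgent"]),
            priority_class=int(d["priority_class"]),
            sbar_note=str(d.get("sbar_note", "")),
            activities=tuple(
                ActivityRequirement(
                    activity_id=str(a["activity_id"]),
                    planned_rounds=int(a["planned_rounds"]),
                    required_doctors=int(a["required_doctors"]),
                    required_nurses=int(a["required_nurses"]),
                )
                for a in d["activities"]
            ),
        )
    except (KeyError, TypeError) as exc:
        raise DeckError(f"malformed profile record at {where}: {exc}") from exc


def write_deck(deck: Sequence[PatientProfile], path: str | Path) -> None:
    """Write a deck as JSON (canonical) or flat CSV (one activity per row)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "profile_id",
                    "urgent",
                    "priority_class",
                    "activity_id",
                    "planned_rounds",
                    "required_doctors",
                    "required_nurses",
                ]
            )
            for p in deck:
                for a in p.activities:
                    w.writerow(
                        [
                            p.profile_id,
                            int(p.urgent),
                            p.priority_class,
                            a.activity_id,
                            a.planned_rounds,
                            a.required_doctors,
                            a.required_nurses,
                        ]
                    )
    else:
        payload = {"format": "edgame-deck", "version": 1, "profiles": [_profile_to_dict(p) for p in deck]}
        path.write_text(json.dumps(payload, indent=2) + "\n")


def read_deck(path: str | Path) -> tuple[PatientProfile, ...]:
    """Read a deck written by :func:`write_deck` (JSON or flat CSV)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise DeckError(f"{path}: empty deck file")
    if path.suffix.lower() == ".csv":
        return _read_deck_csv(path)
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DeckError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    records = payload["profiles"] if isinstance(payload, dict) else payload
    profiles = [
        _profile_from_dict(d, f"{path}: profile #{i + 1}") for i, d in enumerate(records)
    ]
    if not profiles:
        raise DeckError(f"{path}: deck contains no profiles")
    return _validate_deck(profiles)


def _read_deck_csv(path: Path) -> tuple[PatientProfile, ...]:
    rows_by_pid: dict[str, list[dict]] = {}
    meta: dict[str, tuple[bool, int]] = {}
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                pid = row["profile_id"]
                meta[pid] = (bool(int(row["urgent"])), int(row["priority_class"]))
                rows_by_pid.setdefault(pid, []).append(row)
            except (KeyError, TypeError, ValueError) as exc:
                raise DeckError(f"{path}: bad record at line {lineno}: {exc}") from exc
    if not rows_by_pid:
        raise DeckError(f"{path}: deck contains no profiles")
    profiles = []
    for pid, rows in rows_by_pid.items():
        urgent, priority = meta[pid]
        profiles.append(
            PatientProfile(
                profile_id=pid,
                urgent=urgent,
                priority_class=priority,
                activities=tuple(
                    ActivityRequirement(
                        activity_id=r["activity_id"],
                        planned_rounds=int(r["planned_rounds"]),
                        required_doctors=int(r["required_doctors"]),
                        required_nurses=int(r["required_nurses"]),
                    )
                    for r in rows
                ),
            )
        )
    return _validate_deck(profiles)


def write_schedule(schedule: ArrivalSchedule, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["round", "profile_id"])
        for r, batch in enumerate(schedule.arrivals, start=1):
            for pid in batch:
                w.writerow([r, pid])


def read_schedule(path: str | Path, rounds: int | None = None) -> ArrivalSchedule:
    by_round: dict[int, list[str]] = {}
    max_round = 0
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                r = int(row["round"])
            except (KeyError, TypeError, ValueError) as exc:
                raise DeckError(f"{path}: bad record at line {lineno}: {exc}") from exc
            by_round.setdefault(r, []).append(row["profile_id"])
            max_round = max(max_round, r)
    n = rounds if rounds is not None else max_round
    return ArrivalSchedule(
        rounds=max(n, 1),
        arrivals=tuple(tuple(by_round.get(r, ())) for r in range(1, max(n, 1) + 1)),
    )
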