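"""Transcription of telemetry events into participatory behavior codes.

Behavior codes: MR (managing resources), EP (editing profiles),
IC (inviting cooperation), FT (finishing tasks). Stimulus codes: RA
(receiving a scoring update) followed by the indicator announced
(AE/RM/PR/PT). Coding is total and deterministic; event types absent from
the coding map (round markers, arrivals, waits, snapshots, rule
enforcement) are explicitly uncoded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .game_engine import GameEvent
from .scoring import INDICATORS, TokenLedger

__all__ = [
    "BEHAVIOR_CODES",
    "STIMULUS_CODES",
    "DEFAULT_CODING_MAP",
    "CodedSequence",
    "EngagementAttributes",
    "code_events",
    "engagement_attributes",
    "write_sequences",
    "read_sequences",
    "CodingError",
]

BEHAVIOR_CODES = ("MR", "EP", "IC", "FT")
STIMULUS_CODES = ("RA",) + INDICATORS

# event_type -> behavior code; triage admit/refer decisions count as
# confirmed decision results (FT). scoring_update is handled specially
# (RA then the indicator code).
DEFAULT_CODING_MAP: Mapping[str, str] = {
    "allocate_staff": "MR",
    "edit_profile": "EP",
    "broadcast_invite": "IC",
    "activity_complete": "FT",
    "discharge": "FT",
    "triage_admit": "FT",
    "triage_refer_out": "FT",
}

_UNCODED = frozenset(
    {
        "session_start",
        "session_end",
        "round_start",
        "arrival",
        "triage_wait",
        "triage_unstaffed",
        "assign_module",
        "rule_enforcement",
        "activity_tick",
        "resilience_state",
    }
)


class CodingError(ValueError):
    pass


@dataclass
class CodedSequence:
    """Ordered (round, code) stream for one player-role."""

    player_id: str
    elements: list[tuple[int, str]] = field(default_factory=list)

    @property
    def codes(self) -> list[str]:
        return [c for _, c in self.elements]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, c in self.elements:
            out[c] = out.get(c, 0) + 1
        return out

    def behaviors_only(self) -> "CodedSequence":
        return CodedSequence(
            self.player_id,
            [(r, c) for r, c in self.elements if c in BEHAVIOR_CODES],
        )

    def __len__(self) -> int:
        return len(self.elements)


def code_events(
    events: Sequence[GameEvent],
    coding_map: Mapping[str, str] | None = None,
    include_stimuli: bool = True,
) -> dict[str, CodedSequence]:
    """Code a causally ordered log into one sequence per player-role.

    ``scoring_update`` events produce the stimulus pair (RA, indicator) for
    the role that received the update; ``include_stimuli=False`` keeps the
    behavior stream only.
    """
    cmap = dict(DEFAULT_CODING_MAP if coding_map is None else coding_map)
    sequences: dict[str, CodedSequence] = {}

    def seq(role: str) -> CodedSequence:
        if role not in sequences:
            sequences[role] = CodedSequence(role)
        return sequences[role]

    for idx, ev in enumerate(events):
        if ev.event_type == "scoring_update":
            if include_stimuli:
                indicator = ev.payload["indicator"]
                if indicator not in INDICATORS:
                    raise CodingError(f"event #{idx}: unknown indicator {indicator!r}")
                s = seq(ev.actor_role)
                s.elements.append((ev.round, "RA"))
                s.elements.append((ev.round, indicator))
            continue
        if ev.event_type in cmap:
            seq(ev.actor_role).elements.append((ev.round, cmap[ev.event_type]))
        elif ev.event_type in _UNCODED:
            continue
        else:
            raise CodingError(f"event #{idx}: unknown event_type {ev.event_type!r}")

    # roles that emitted no codable events still get empty sequences
    for ev in events:
        if ev.event_type == "session_start":
            for role in ev.payload.get("module_roles", []):
                seq(role)
            seq("triage")
    return sequences


@dataclass(frozen=True)
class EngagementAttributes:
    """Per-player engagement record feeding the regression dataset."""

    player_id: str
    n_MR: int
    n_EP: int
    n_IC: int
    n_FT: int
    time_on_task: int  # minutes: rounds with >=1 behavior x minutes_per_round
    performance: int  # total tokens for the role


def engagement_attributes(
    sequence: CodedSequence,
    ledger: TokenLedger,
    minutes_per_round: int = 30,
) -> EngagementAttributes:
    """Derive engagement counts, time on task, and token performance."""
    counts = sequence.counts()
    behavior_rounds = {r for r, c in sequence.elements if c in BEHAVIOR_CODES}
    return EngagementAttributes(
        player_id=sequence.player_id,
        n_MR=counts.get("MR", 0),
        n_EP=counts.get("EP", 0),
        n_IC=counts.get("IC", 0),
        n_FT=counts.get("FT", 0),
        time_on_task=len(behavior_rounds) * minutes_per_round,
        performance=ledger.total(sequence.player_id),
    )


def write_sequences(sequences: Mapping[str, CodedSequence], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["player_id", "ordinal", "round", "code"])
        for pid in sorted(sequences):
            for i, (r, c) in enumerate(sequences[pid].elements):
                w.writerow([pid, i, r, c])


def read_sequences(path: str | Path) -> dict[str, CodedSequence]:
    sequences: dict[str, CodedSequence] = {}
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                pid = row["player_id"]
                if pid not in sequences:
                    sequences[pid] = CodedSequence(pid)
                sequences[pid].elements.append((int(row["round"]), row["code"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise CodingError(f"{path}: bad record at line {lineno}: {exc}") from exc
    return sequences
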