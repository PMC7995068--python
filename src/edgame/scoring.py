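"""Token-based scoring mechanic over four logistical indicators.

Indicators and default token table (red module / normal module / triage):

* production throughput (PT): +16 / +4 on discharge; triage earns a quarter
  of the receiving module's reward but loses 1 token per 2 rejections.
* activity execution (AE): delay buckets +25/+50/+75/+100 percent of the
  plan map to -4/-8/-12/-16 (red) and -1/-2/-3/-4 (normal); triage N/A.
  Delays below 25 percent are free; delays above 100 percent cap at the
  100-percent bucket. Early completion earns nothing.
* resource management (RM): -4 / -1 / -1 per under-staffed activity-round.
* production resilience (PR): -4 / -1 when a module ends a round with zero
  free doctors; triage N/A.

Scoring is a pure, idempotent function of the telemetry event log; every
ledger delta is traceable to the causing event.  Calibration targets a
roughly 6:1 count ratio of positive to negative feedback events.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "INDICATORS",
    "ScoringRules",
    "LedgerEntry",
    "TokenLedger",
    "FeedbackRatio",
    "ScoringError",
    "score_throughput",
    "score_rejections",
    "score_activity_execution",
    "score_resource_management",
    "score_resilience",
    "apply_scoring",
    "feedback_ratio",
    "write_ledger",
]

INDICATORS = ("PT", "AE", "RM", "PR")

_AE_THRESHOLDS = (0.25, 0.50, 0.75, 1.00)


class ScoringError(ValueError):
    """Raised for malformed logs or invalid scorer arguments."""


def _round_half_away(x: Fraction) -> int:
    return int(math.floor(x + Fraction(1, 2))) if x >= 0 else -int(math.floor(-x + Fraction(1, 2)))


@dataclass(frozen=True)
class ScoringRules:
    """Token table; defaults mirror the published mechanic."""

    throughput_reward: Mapping[str, int] = field(
        default_factory=lambda: {"red": 16, "normal": 4}
    )
    triage_share: Fraction = Fraction(1, 4)
    rejections_per_penalty: int = 2
    ae_penalties: Mapping[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: {"red": (-4, -8, -12, -16), "normal": (-1, -2, -3, -4)}
    )
    rm_penalty: Mapping[str, int] = field(
        default_factory=lambda: {"red": -4, "normal": -1, "triage": -1}
    )
    pr_penalty: Mapping[str, int] = field(default_factory=lambda: {"red": -4, "normal": -1})

    def validate(self) -> None:
        if any(v <= 0 for v in self.throughput_reward.values()):
            raise ScoringError("throughput rewards must be positive")
        for table in (self.ae_penalties["red"], self.ae_penalties["normal"]):
            if any(v >= 0 for v in table):
                raise ScoringError("activity-execution penalties must be negative")
        if any(v >= 0 for v in self.rm_penalty.values()):
            raise ScoringError("resource-management penalties must be negative")
        if any(v >= 0 for v in self.pr_penalty.values()):
            raise ScoringError("resilience penalties must be negative")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "throughput_reward": dict(self.throughput_reward),
            "triage_share": [self.triage_share.numerator, self.triage_share.denominator],
            "rejections_per_penalty": self.rejections_per_penalty,
            "ae_penalties": {k: list(v) for k, v in self.ae_penalties.items()},
            "rm_penalty": dict(self.rm_penalty),
            "pr_penalty": dict(self.pr_penalty),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoringRules":
        doc = json.loads(Path(path).read_text())
        num, den = doc["triage_share"]
        rules = cls(
            throughput_reward={k: int(v) for k, v in doc["throughput_reward"].items()},
            triage_share=Fraction(num, den),
            rejections_per_penalty=int(doc["rejections_per_penalty"]),
            ae_penalties={k: tuple(int(x) for x in v) for k, v in doc["ae_penalties"].items()},
            rm_penalty={k: int(v) for k, v in doc["rm_penalty"].items()},
            pr_penalty={k: int(v) for k, v in doc["pr_penalty"].items()},
        )
        rules.validate()
        return rules


@dataclass(frozen=True)
class LedgerEntry:
    round: int
    role: str
    indicator: str
    delta: int
    cause: int  # index of the causing event in the log


class TokenLedger:
    """Per-role ordered sequence of signed scoring deltas."""

    def __init__(self, entries: Iterable[LedgerEntry] = ()) -> None:
        self.entries: list[LedgerEntry] = list(entries)

    def append(self, entry: LedgerEntry) -> None:
        self.entries.append(entry)

    def roles(self) -> list[str]:
        return sorted({e.role for e in self.entries})

    def total(self, role: str | None = None) -> int:
        return sum(e.delta for e in self.entries if role is None or e.role == role)

    def totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.role] = out.get(e.role, 0) + e.delta
        return out

    def by_indicator(self, role: str | None = None) -> dict[str, int]:
        out = {ind: 0 for ind in INDICATORS}
        for e in self.entries:
            if role is None or e.role == role:
                out[e.indicator] += e.delta
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TokenLedger) and self.entries == other.entries


# ---------------------------------------------------------------------------
# per-indicator scorers


def _role_kind(role: str, red_role: str) -> str:
    if role == "triage":
        return "triage"
    return "red" if role == red_role else "normal"


def score_throughput(is_red: bool, rules: ScoringRules | None = None) -> tuple[int, int]:
    """Return ``(module_delta, triage_delta)`` for one discharge."""
    rules = rules or ScoringRules()
    reward = rules.throughput_reward["red" if is_red else "normal"]
    share = _round_half_away(Fraction(reward) * rules.triage_share)
    return reward, share


def score_rejections(count: int, rules: ScoringRules | None = None) -> int:
    """Cumulative triage penalty: -1 token per ``rejections_per_penalty``."""
    if count < 0:
        raise ScoringError("rejection count must be non-negative")
    rules = rules or ScoringRules()
    return -(count // rules.rejections_per_penalty)


def score_activity_execution(
    planned_rounds: int,
    actual_rounds: int,
    role_kind: str,
    rules: ScoringRules | None = None,
) -> int:
    """Delay-bucket penalty for one completed activity.

    ``role_kind`` is one of ``red``/``normal``/``triage``; triage is exempt.
    """
    if planned_rounds < 1:
        raise ScoringError("planned_rounds must be >= 1")
    if actual_rounds < planned_rounds:
        raise ScoringError("actual_rounds < planned_rounds: early completion carries no bonus")
    if role_kind == "triage":
        return 0
    rules = rules or ScoringRules()
    delay = (actual_rounds - planned_rounds) / planned_rounds
    bucket = -1
    for i, thr in enumerate(_AE_THRESHOLDS):
        if delay >= thr:
            bucket = i
    if bucket < 0:
        return 0
    return rules.ae_penalties[role_kind][bucket]


def score_resource_management(role_kind: str, rules: ScoringRules | None = None) -> int:
    """Penalty for one under-staffed activity-round (or unstaffed triage round)."""
    rules = rules or ScoringRules()
    return rules.rm_penalty[role_kind]


def score_resilience(role_kind: str, free_doctors: int, rules: ScoringRules | None = None) -> int:
    """Round-end penalty when a module has no free doctor; triage exempt."""
    if role_kind == "triage" or free_doctors > 0:
        return 0
    rules = rules or ScoringRules()
    return rules.pr_penalty[role_kind]


# ---------------------------------------------------------------------------
# log scorer


def apply_scoring(events: Sequence, rules: ScoringRules | None = None) -> TokenLedger:
    """Score a causally ordered event log into a :class:`TokenLedger`.

    Consumes cause events only (discharges, referrals, completions, stalled
    ticks, round-end resilience snapshots); any ``scoring_update`` events the
    engine wrote into the same log are ignored, so re-running is idempotent
    and the ledger can be cross-checked against the engine's own updates.
    """
    rules = rules or ScoringRules()
    red_role = "module_1"
    ledger = TokenLedger()
    rejections = 0
    for idx, ev in enumerate(events):
        etype = getattr(ev, "event_type", None)
        if etype is None:
            raise ScoringError(f"malformed event at index {idx}: {ev!r}")
        payload = ev.payload
        if etype == "session_start":
            red_role = payload["red_role"]
        elif etype == "discharge":
            role = payload["module_role"]
            is_red = role == red_role
            mod_delta, triage_delta = score_throughput(is_red, rules)
            ledger.append(LedgerEntry(ev.round, role, "PT", mod_delta, idx))
            if triage_delta:
                ledger.append(LedgerEntry(ev.round, "triage", "PT", triage_delta, idx))
        elif etype == "triage_refer_out":
            rejections += 1
            if rejections % rules.rejections_per_penalty == 0:
                ledger.append(LedgerEntry(ev.round, "triage", "PT", -1, idx))
        elif etype == "activity_complete":
            role = payload["module_role"]
            delta = score_activity_execution(
                payload["planned_rounds"],
                payload["actual_rounds"],
                _role_kind(role, red_role),
                rules,
            )
            if delta:
                ledger.append(LedgerEntry(ev.round, role, "AE", delta, idx))
        elif etype == "activity_tick":
            if payload.get("stalled"):
                role = payload["module_role"]
                delta = score_resource_management(_role_kind(role, red_role), rules)
                ledger.append(LedgerEntry(ev.round, role, "RM", delta, idx))
        elif etype == "triage_unstaffed":
            ledger.append(
                LedgerEntry(ev.round, "triage", "RM", score_resource_management("triage", rules), idx)
            )
        elif etype == "resilience_state":
            role = payload["module_role"]
            kind = _role_kind(role, red_role)
            delta = score_resilience(kind, payload["free_doctors"], rules)
            if delta:
                ledger.append(LedgerEntry(ev.round, role, "PR", delta, idx))
    return ledger


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class FeedbackRatio:
    positives: int
    negatives: int

    @property
    def ratio(self) -> float:
        if self.negatives == 0:
            return math.inf if self.positives else math.nan
        return self.positives / self.negatives

    @property
    def undefined(self) -> bool:
        return self.negatives == 0


def feedback_ratio(ledger: TokenLedger) -> dict[str, FeedbackRatio]:
    """Count ratio of positive to negative deltas, per role and overall."""
    out: dict[str, FeedbackRatio] = {}
    pos_by: dict[str, int] = {}
    neg_by: dict[str, int] = {}
    for e in ledger.entries:
        if e.delta > 0:
            pos_by[e.role] = pos_by.get(e.role, 0) + 1
        elif e.delta < 0:
            neg_by[e.role] = neg_by.get(e.role, 0) + 1
    for role in sorted(set(pos_by) | set(neg_by)):
        out[role] = FeedbackRatio(pos_by.get(role, 0), neg_by.get(role, 0))
    out["overall"] = FeedbackRatio(sum(pos_by.values()), sum(neg_by.values()))
    return out


def write_ledger(ledger: TokenLedger, path: str | Path) -> None:
    """Export the ledger as CSV with per-role running totals."""
    running: dict[str, int] = {}
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["role", "round", "indicator", "delta", "total"])
        for e in ledger.entries:
            running[e.role] = running.get(e.role, 0) + e.delta
            w.writerow([e.role, e.round, e.indicator, e.delta, running[e.role]])
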