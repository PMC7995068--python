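"""Scoring mechanic tests, including an independent naive per-event oracle."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgame.game_engine import GameEvent
from edgame.scoring import (
    LedgerEntry,
    ScoringError,
    ScoringRules,
    TokenLedger,
    apply_scoring,
    feedback_ratio,
    score_activity_execution,
    score_rejections,
    score_resilience,
    score_resource_management,
    score_throughput,
)

RED = "module_1"
NORMALS = ["module_2", "module_3", "module_4", "module_5"]


# ---------------------------------------------------------------------------
# independent oracle: a deliberately naive scorer over the same event schema


def naive_score(events):
    """Brute-force re-implementation: one pass, table lookups only."""
    totals = {}

    def add(role, delta):
        totals[role] = totals.get(role, 0) + delta

    rejections = 0
    red_role = "module_1"
    for ev in events:
        t = ev.event_type
        p = ev.payload
        if t == "session_start":
            red_role = p["red_role"]
        elif t == "discharge":
            if p["module_role"] == red_role:
                add(p["module_role"], 16)
                add("triage", 4)
            else:
                add(p["module_role"], 4)
                add("triage", 1)
        elif t == "triage_refer_out":
            rejections += 1
            if rejections % 2 == 0:
                add("triage", -1)
        elif t == "activity_complete":
            delay = (p["actual_rounds"] - p["planned_rounds"]) / p["planned_rounds"]
            table = [-4, -8, -12, -16] if p["module_role"] == red_role else [-1, -2, -3, -4]
            if delay >= 1.00:
                add(p["module_role"], table[3])
            elif delay >= 0.75:
                add(p["module_role"], table[2])
            elif delay >= 0.50:
                add(p["module_role"], table[1])
            elif delay >= 0.25:
                add(p["module_role"], table[0])
        elif t == "activity_tick" and p.get("stalled"):
            add(p["module_role"], -4 if p["module_role"] == red_role else -1)
        elif t == "triage_unstaffed":
            add("triage", -1)
        elif t == "resilience_state" and p["free_doctors"] == 0:
            add(p["module_role"], -4 if p["module_role"] == red_role else -1)
    return totals


def random_log(rng, n_events=60):
    events = [
        GameEvent(0, "system", "session_start", {"red_role": RED, "module_roles": [RED, *NORMALS]})
    ]
    roles = [RED, *NORMALS]
    for i in range(n_events):
        rnd = int(rng.integers(1, 13))
        kind = rng.choice(
            ["discharge", "triage_refer_out", "activity_complete", "activity_tick", "resilience_state"]
        )
        role = str(rng.choice(roles))
        if kind == "discharge":
            ev = GameEvent(rnd, role, "discharge", {"profile_id": f"P{i}", "module_role": role})
        elif kind == "triage_refer_out":
            ev = GameEvent(rnd, "triage", "triage_refer_out", {"profile_id": f"P{i}"})
        elif kind == "activity_complete":
            planned = int(rng.integers(1, 5))
            actual = planned + int(rng.integers(0, 8))
            ev = GameEvent(
                rnd,
                role,
                "activity_complete",
                {"module_role": role, "planned_rounds": planned, "actual_rounds": actual},
            )
        elif kind == "activity_tick":
            ev = GameEvent(
                rnd,
                role,
                "activity_tick",
                {"module_role": role, "stalled": bool(rng.random() < 0.5), "progress": 0},
            )
        else:
            ev = GameEvent(
                rnd, role, "resilience_state",
                {"module_role": role, "free_doctors": int(rng.integers(0, 3))},
            )
        events.append(ev)
    return events


# ---------------------------------------------------------------------------


class TestThroughput:
    def test_red_discharge(self):
        assert score_throughput(is_red=True) == (16, 4)

    def test_normal_discharge(self):
        assert score_throughput(is_red=False) == (4, 1)

    def test_triage_share_is_quarter(self):
        rules = ScoringRules()
        for is_red in (True, False):
            mod, tri = score_throughput(is_red, rules)
            assert tri == round(Fraction(mod) * Fraction(1, 4))

    def test_fractional_share_rounds_half_away_from_zero(self):
        rules = ScoringRules(throughput_reward={"red": 16, "normal": 2})
        assert score_throughput(False, rules) == (2, 1)  # 0.5 -> 1


class TestRejections:
    @pytest.mark.parametrize("count,expected", [(0, 0), (1, 0), (2, -1), (3, -1), (4, -2), (5, -2)])
    def test_floor_rule(self, count, expected):
        assert score_rejections(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ScoringError):
            score_rejections(-1)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_integer_division_oracle(self, count):
        assert score_rejections(count) == -(count // 2)


class TestActivityExecution:
    # oracle: direct bucket-table lookup
    @pytest.mark.parametrize(
        "planned,actual,role,expected",
        [
            (4, 4, "red", 0),  # on time
            (4, 5, "red", -4),  # +25%
            (4, 6, "red", -8),  # +50%
            (4, 7, "red", -12),  # +75%
            (4, 8, "red", -16),  # +100%
            (4, 5, "normal", -1),
            (4, 6, "normal", -2),
            (4, 7, "normal", -3),
            (4, 8, "normal", -4),
            (2, 5, "normal", -4),  # 150% capped at the 100% bucket
            (10, 11, "red", 0),  # 10% below first bucket
            (3, 4, "normal", -1),  # 33.3% -> 25% bucket
            (4, 4, "triage", 0),
            (4, 8, "triage", 0),  # triage exempt
        ],
    )
    def test_bucket_table(self, planned, actual, role, expected):
        assert score_activity_execution(planned, actual, role) == expected

    def test_early_completion_is_error(self):
        with pytest.raises(ScoringError, match="early completion"):
            score_activity_execution(4, 3, "red")

    @given(
        planned=st.integers(min_value=1, max_value=20),
        extra=st.integers(min_value=0, max_value=60),
        role=st.sampled_from(["red", "normal"]),
    )
    def test_oracle_equivalence(self, planned, extra, role):
        delay = extra / planned
        table = {"red": [-4, -8, -12, -16], "normal": [-1, -2, -3, -4]}[role]
        if delay >= 1.0:
            expected = table[3]
        elif delay >= 0.75:
            expected = table[2]
        elif delay >= 0.5:
            expected = table[1]
        elif delay >= 0.25:
            expected = table[0]
        else:
            expected = 0
        assert score_activity_execution(planned, planned + extra, role) == expected


class TestResourceManagementAndResilience:
    def test_rm_penalties(self):
        assert score_resource_management("red") == -4
        assert score_resource_management("normal") == -1
        assert score_resource_management("triage") == -1

    def test_pr_penalties(self):
        assert score_resilience("red", free_doctors=0) == -4
        assert score_resilience("normal", free_doctors=0) == -1
        assert score_resilience("red", free_doctors=1) == 0
        assert score_resilience("triage", free_doctors=0) == 0  # N/A


class TestRulesTable:
    def test_red_is_four_times_normal(self):
        rules = ScoringRules()
        assert rules.throughput_reward["red"] == 4 * rules.throughput_reward["normal"]
        for r, n in zip(rules.ae_penalties["red"], rules.ae_penalties["normal"]):
            assert r == 4 * n
        assert rules.rm_penalty["red"] == 4 * rules.rm_penalty["normal"]
        assert rules.pr_penalty["red"] == 4 * rules.pr_penalty["normal"]

    def test_signs(self):
        rules = ScoringRules()
        rules.validate()
        assert all(v > 0 for v in rules.throughput_reward.values())
        assert all(v < 0 for vs in rules.ae_penalties.values() for v in vs)

    def test_json_round_trip(self, tmp_path):
        rules = ScoringRules()
        rules.to_json(tmp_path / "rules.json")
        assert ScoringRules.from_json(tmp_path / "rules.json") == rules


class TestApplyScoring:
    def test_empty_log(self):
        ledger = apply_scoring([])
        assert ledger.totals() == {}
        assert ledger.total() == 0

    def test_single_red_discharge(self):
        events = [
            GameEvent(0, "system", "session_start", {"red_role": RED}),
            GameEvent(1, RED, "discharge", {"profile_id": "P1", "module_role": RED}),
        ]
        ledger = apply_scoring(events)
        assert ledger.totals() == {RED: 16, "triage": 4}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        events = random_log(rng)
        assert apply_scoring(events) == apply_scoring(events)

    def test_malformed_event_rejected(self):
        with pytest.raises(ScoringError, match="index 0"):
            apply_scoring([{"not": "an event"}])

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_sample(self, seed):
        rng = np.random.default_rng(seed)
        events = random_log(rng)
        assert apply_scoring(events).totals() == naive_score(events)

    def test_oracle_equivalence_1000_random_logs(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            events = random_log(rng, n_events=40)
            assert apply_scoring(events).totals() == naive_score(events)

    def test_ledger_conservation(self):
        rng = np.random.default_rng(42)
        events = random_log(rng)
        ledger = apply_scoring(events)
        totals = ledger.totals()
        for role in totals:
            assert totals[role] == sum(e.delta for e in ledger.entries if e.role == role)
        assert ledger.total() == sum(totals.values())

    def test_monotonicity(self):
        rng = np.random.default_rng(7)
        events = random_log(rng)
        before = apply_scoring(events).totals()
        plus = events + [GameEvent(12, RED, "discharge", {"profile_id": "X", "module_role": RED})]
        after = apply_scoring(plus).totals()
        for role in before:
            assert after.get(role, 0) >= before[role]
        minus = events + [
            GameEvent(12, RED, "activity_tick", {"module_role": RED, "stalled": True})
        ]
        after = apply_scoring(minus).totals()
        for role in before:
            assert after.get(role, 0) <= before[role]


class TestFeedbackRatio:
    def test_simple_ratio(self):
        ledger = TokenLedger(
            [LedgerEntry(1, "r", "PT", +4, 0) for _ in range(12)]
            + [LedgerEntry(1, "r", "RM", -1, 0) for _ in range(2)]
        )
        assert feedback_ratio(ledger)["overall"].ratio == 6.0

    def test_all_positive_flagged_infinite(self):
        ledger = TokenLedger([LedgerEntry(1, "r", "PT", +4, 0)])
        fr = feedback_ratio(ledger)["overall"]
        assert fr.undefined
        assert math.isinf(fr.ratio)

    def test_per_role_breakdown(self):
        ledger = TokenLedger(
            [LedgerEntry(1, "a", "PT", 4, 0), LedgerEntry(1, "b", "RM", -1, 1)]
        )
        ratios = feedback_ratio(ledger)
        assert ratios["a"].positives == 1 and ratios["a"].negatives == 0
        assert ratios["b"].negatives == 1
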