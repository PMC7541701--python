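"""Morra plays, validity rules, round adjudication and match simulation.

In Morra each player simultaneously shows a hand-number (1-5 fingers) and
calls a number from 2 to 10; a player scores when the call equals the sum
of both hands.  A play is *possible* only when the call can still be
reached given the shown hand: ``1 <= call - hand <= 5``, which leaves
exactly 25 valid hand/call combinations.  Beginners commonly break this
constraint in three ways (call more than hand+5, call equal to the hand,
call below the hand); :func:`validate_play` distinguishes these.

Matches are played to a target score (traditionally 16 for two-a-side team
play, 10 for singles).  In team mode the scorer of a round stays on and
the losing side substitutes its active player.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Play",
    "PlayValidity",
    "RoundOutcome",
    "MatchRecord",
    "InvalidPlayError",
    "VALID_PLAYS",
    "validate_play",
    "adjudicate_round",
    "build_payoff_matrix",
    "UniformRandomAgent",
    "MarkovHandAgent",
    "simulate_match",
    "extract_hand_sequences",
    "match_to_frame",
    "write_match",
    "read_match",
]

# Reason codes for invalid plays.
REASON_HAND_RANGE = "hand out of range"
REASON_CALL_RANGE = "call out of range"
REASON_CALL_TOO_HIGH = "call exceeds hand+5"
REASON_CALL_EQUALS_HAND = "call equals hand"
REASON_CALL_BELOW_HAND = "call below hand"


@dataclass(frozen=True)
class Play:
    """One Morra action: ``hand`` fingers shown while calling ``call``."""

    hand: int
    call: int

    def __post_init__(self) -> None:
        if not isinstance(self.hand, (int, np.integer)) or isinstance(self.hand, bool):
            raise TypeError(f"hand must be an integer, got {self.hand!r}")
        if not isinstance(self.call, (int, np.integer)) or isinstance(self.call, bool):
            raise TypeError(f"call must be an integer, got {self.call!r}")
        object.__setattr__(self, "hand", int(self.hand))
        object.__setattr__(self, "call", int(self.call))

    @property
    def is_valid(self) -> bool:
        return validate_play(self.hand, self.call).valid

    def label(self) -> str:
        return f"{self.hand}, {self.call}"


@dataclass(frozen=True)
class PlayValidity:
    valid: bool
    reason: str | None = None


class InvalidPlayError(ValueError):
    def __init__(self, play: Play, reason: str):
        super().__init__(f"invalid play {play.label()}: {reason}")
        self.play = play
        self.reason = reason


def validate_play(hand: int, call: int) -> PlayValidity:
    """Check a hand/call combination, distinguishing the beginner errors.

    A play is valid iff hand is 1-5, call is 2-10 and ``1 <= call - hand <= 5``
    (the opponent must be able to show ``call - hand`` fingers).
    """
    for v, name in ((hand, "hand"), (call, "call")):
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            raise TypeError(f"{name} must be an integer, got {v!r}")
    if not 1 <= hand <= 5:
        return PlayValidity(False, REASON_HAND_RANGE)
    if not 2 <= call <= 10:
        return PlayValidity(False, REASON_CALL_RANGE)
    if call - hand > 5:
        return PlayValidity(False, REASON_CALL_TOO_HIGH)
    if call == hand:
        return PlayValidity(False, REASON_CALL_EQUALS_HAND)
    if call < hand:
        return PlayValidity(False, REASON_CALL_BELOW_HAND)
    return PlayValidity(True)


#: The 25 valid plays, sorted by (hand, call) — the printed row order of the
#: winning-combinations matrix.
VALID_PLAYS: tuple[Play, ...] = tuple(
    Play(h, c) for h in range(1, 6) for c in range(2, 11) if validate_play(h, c).valid
)


@dataclass(frozen=True)
class RoundOutcome:
    """Adjudicated result of one round. ``winner`` is 'A', 'B' or None."""

    play_a: Play
    play_b: Play
    winner: str | None

    @property
    def total(self) -> int:
        return self.play_a.hand + self.play_b.hand


def adjudicate_round(play_a: Play, play_b: Play) -> RoundOutcome:
    """Score one round: a side wins iff it alone called the sum of hands."""
    for p in (play_a, play_b):
        v = validate_play(p.hand, p.call)
        if not v.valid:
            raise InvalidPlayError(p, v.reason)
    total = play_a.hand + play_b.hand
    a_hit = play_a.call == total
    b_hit = play_b.call == total
    if a_hit and not b_hit:
        winner = "A"
    elif b_hit and not a_hit:
        winner = "B"
    else:
        winner = None
    return RoundOutcome(play_a=play_a, play_b=play_b, winner=winner)


def build_payoff_matrix() -> pd.DataFrame:
    """25x25 outcome table from player B's perspective.

    Rows are B's plays and columns A's plays, both in (hand, call) order;
    each cell holds 'B', 'A' or '' (no winner).
    """
    labels = [p.label() for p in VALID_PLAYS]
    data = [
        [adjudicate_round(pa, pb).winner or "" for pa in VALID_PLAYS]
        for pb in VALID_PLAYS
    ]
    return pd.DataFrame(data, index=labels, columns=labels)


class UniformRandomAgent:
    """Uniform hand, call = own hand + uniform guess of the opponent's hand."""

    def __call__(self, rng: np.random.Generator) -> Play:
        hand = int(rng.integers(1, 6))
        return Play(hand, hand + int(rng.integers(1, 6)))


class MarkovHandAgent:
    """Agent whose hand-numbers follow a first-order Markov preference model.

    The hand channel is delegated to an :class:`~morra.agents.AgentConfig`
    sampler; the call is the agent's own hand plus a uniform guess of the
    opponent's hand (call strategy is not a studied quantity here).  State
    (the previous hand) persists across benched rounds.
    """

    def __init__(self, config, under_load: bool = False):
        self.config = config
        self.under_load = under_load
        self._prev: int | None = None

    def __call__(self, rng: np.random.Generator) -> Play:
        from .agents import _step  # local import to avoid a cycle

        hand = _step(self.config, self.under_load, self._prev, rng)
        self._prev = hand
        return Play(hand, hand + int(rng.integers(1, 6)))


@dataclass(frozen=True)
class MatchRecord:
    """Full record of one match.

    ``lineup_history[i]`` holds the (side-A player id, side-B player id)
    that acted in round ``i``; ``scores`` are final cumulative points.
    """

    rounds: tuple[RoundOutcome, ...]
    lineup_history: tuple[tuple[str, str], ...]
    scores: dict[str, int]
    target_score: int
    team_mode: bool
    invalid_play_resamples: int = 0

    @property
    def winner(self) -> str:
        return "A" if self.scores["A"] == self.target_score else "B"


def _draw_valid(agent, rng: np.random.Generator, on_invalid: str, counter: list[int]) -> Play:
    for _ in range(1000):
        play = agent(rng)
        v = validate_play(play.hand, play.call)
        if v.valid:
            return play
        if on_invalid == "abort":
            raise InvalidPlayError(play, v.reason)
        counter[0] += 1
    raise RuntimeError("agent failed to produce a valid play in 1000 attempts")


def simulate_match(
    agents_a: Sequence[Callable] | Callable,
    agents_b: Sequence[Callable] | Callable,
    target_score: int = 16,
    team_mode: bool = False,
    seed: int | None = None,
    on_invalid: str = "resample",
) -> MatchRecord:
    """Play rounds until one side first reaches ``target_score``.

    In team mode each side supplies two agents; after a scored round the
    scorer stays on and the losing side substitutes its active player (tie
    rounds score for neither side and the lineup is unchanged).  Invalid
    agent plays are rejected and resampled by default (``on_invalid=
    'resample'``, counted in the record) or raise (``'abort'``).
    """
    if target_score < 1:
        raise ValueError("target_score must be >= 1")
    if on_invalid not in ("resample", "abort"):
        raise ValueError("on_invalid must be 'resample' or 'abort'")
    team_a = list(agents_a) if isinstance(agents_a, (list, tuple)) else [agents_a]
    team_b = list(agents_b) if isinstance(agents_b, (list, tuple)) else [agents_b]
    expected = 2 if team_mode else 1
    if len(team_a) != expected or len(team_b) != expected:
        raise ValueError(f"each side needs exactly {expected} agent(s)")

    rng = np.random.default_rng(seed)
    scores = {"A": 0, "B": 0}
    active = {"A": 0, "B": 0}
    rounds: list[RoundOutcome] = []
    lineup: list[tuple[str, str]] = []
    resamples = [0]

    while max(scores.values()) < target_score:
        ia, ib = active["A"], active["B"]
        play_a = _draw_valid(team_a[ia], rng, on_invalid, resamples)
        play_b = _draw_valid(team_b[ib], rng, on_invalid, resamples)
        outcome = adjudicate_round(play_a, play_b)
        rounds.append(outcome)
        lineup.append((f"A{ia}", f"B{ib}"))
        if outcome.winner is not None:
            scores[outcome.winner] += 1
            if team_mode and max(scores.values()) < target_score:
                loser = "B" if outcome.winner == "A" else "A"
                active[loser] = 1 - active[loser]

    return MatchRecord(
        rounds=tuple(rounds),
        lineup_history=tuple(lineup),
        scores=scores,
        target_score=target_score,
        team_mode=team_mode,
        invalid_play_resamples=resamples[0],
    )


def extract_hand_sequences(match: MatchRecord):
    """One hand-number sequence per participating player, in round order.

    Rounds in which a player was benched contribute nothing to that
    player's sequence.  Returns a dict keyed by player id ('A0', 'B1', ...).
    """
    from .metrics import ResponseSequence

    if not match.rounds:
        raise ValueError("match has no rounds")
    values: dict[str, list[int]] = {}
    for outcome, (pid_a, pid_b) in zip(match.rounds, match.lineup_history):
        values.setdefault(pid_a, []).append(outcome.play_a.hand)
        values.setdefault(pid_b, []).append(outcome.play_b.hand)
    return {
        pid: ResponseSequence(tuple(v), participant_id=pid)
        for pid, v in sorted(values.items())
    }


def match_to_frame(match: MatchRecord) -> pd.DataFrame:
    """One row per round: lineup, hands, calls, sum and winner."""
    return pd.DataFrame(
        {
            "round": range(1, len(match.rounds) + 1),
            "player_a": [pa for pa, _ in match.lineup_history],
            "player_b": [pb for _, pb in match.lineup_history],
            "hand_a": [r.play_a.hand for r in match.rounds],
            "call_a": [r.play_a.call for r in match.rounds],
            "hand_b": [r.play_b.hand for r in match.rounds],
            "call_b": [r.play_b.call for r in match.rounds],
            "sum": [r.total for r in match.rounds],
            "winner": [r.winner or "" for r in match.rounds],
        }
    )


def write_match(match: MatchRecord, rounds_path, report_path) -> None:
    """Serialize a match to a rounds CSV plus a structured JSON report."""
    match_to_frame(match).to_csv(rounds_path, index=False)
    report = {
        "target_score": match.target_score,
        "team_mode": match.team_mode,
        "scores": match.scores,
        "winner": match.winner,
        "n_rounds": len(match.rounds),
        "invalid_play_resamples": match.invalid_play_resamples,
    }
    Path(report_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_match(rounds_path, report_path) -> MatchRecord:
    """Inverse of :func:`write_match`; round-trips losslessly."""
    frame = pd.read_csv(rounds_path, keep_default_na=False)
    report = json.loads(Path(report_path).read_text())
    rounds = tuple(
        RoundOutcome(
            play_a=Play(int(r.hand_a), int(r.call_a)),
            play_b=Play(int(r.hand_b), int(r.call_b)),
            winner=r.winner or None,
        )
        for r in frame.itertuples()
    )
    lineup = tuple((str(r.player_a), str(r.player_b)) for r in frame.itertuples())
    return MatchRecord(
        rounds=rounds,
        lineup_history=lineup,
        scores={k: int(v) for k, v in report["scores"].items()},
        target_score=int(report["target_score"]),
        team_mode=bool(report["team_mode"]),
        invalid_play_resamples=int(report["invalid_play_resamples"]),
    )
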