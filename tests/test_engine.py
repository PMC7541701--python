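"""Tests for play validity, round adjudication and match simulation."""

import numpy as np
import pytest

from morra.engine import (
    InvalidPlayError,
    MatchRecord,
    MarkovHandAgent,
    Play,
    RoundOutcome,
    UniformRandomAgent,
    VALID_PLAYS,
    adjudicate_round,
    build_payoff_matrix,
    extract_hand_sequences,
    match_to_frame,
    read_match,
    simulate_match,
    validate_play,
    write_match,
)
from morra.agents import AgentConfig
from payoff_fixture import PRINTED_B_WINS


class TestValidatePlay:
    @pytest.mark.parametrize(
        "hand,call,reason",
        [
            (1, 7, "call exceeds hand+5"),
            (3, 3, "call equals hand"),
            (4, 3, "call below hand"),
            (0, 4, "hand out of range"),
            (6, 8, "hand out of range"),
            (2, 11, "call out of range"),
            (2, 1, "call out of range"),
        ],
    )
    def test_invalid_plays_carry_reason_codes(self, hand, call, reason):
        v = validate_play(hand, call)
        assert not v.valid
        assert v.reason == reason

    @pytest.mark.parametrize("hand,call", [(1, 2), (1, 6), (5, 6), (5, 10), (3, 7)])
    def test_valid_plays(self, hand, call):
        assert validate_play(hand, call).valid

    def test_non_integer_input_raises(self):
        with pytest.raises(TypeError):
            validate_play(1.5, 4)
        with pytest.raises(TypeError):
            Play(1, "4")

    def test_exactly_25_valid_plays_in_printed_order(self):
        assert len(VALID_PLAYS) == 25
        assert [p.label() for p in VALID_PLAYS] == list(PRINTED_B_WINS)


class TestAdjudication:
    def test_single_correct_call_wins(self):
        # sum is 2; only B called it
        out = adjudicate_round(Play(1, 3), Play(1, 2))
        assert out.winner == "B"
        assert out.total == 2

    def test_both_correct_is_a_tie(self):
        assert adjudicate_round(Play(1, 2), Play(1, 2)).winner is None

    def test_neither_correct_is_a_tie(self):
        assert adjudicate_round(Play(2, 6), Play(3, 7)).winner is None

    def test_invalid_play_raises_with_reason(self):
        with pytest.raises(InvalidPlayError, match="call equals hand"):
            adjudicate_round(Play(3, 3), Play(1, 2))


class TestPayoffMatrix:
    def test_reproduces_every_printed_cell(self):
        matrix = build_payoff_matrix()
        for b_label, row in matrix.iterrows():
            marked = tuple(a_label for a_label, v in row.items() if v == "B")
            assert marked == PRINTED_B_WINS[b_label]

    def test_four_b_wins_per_row_and_100_total(self):
        matrix = build_payoff_matrix()
        per_row = (matrix == "B").sum(axis=1)
        assert (per_row == 4).all()
        assert int((matrix == "B").sum().sum()) == 100

    def test_mirror_antisymmetry(self):
        matrix = build_payoff_matrix()
        for p in matrix.index:
            for q in matrix.columns:
                mirrored = {"B": "A", "A": "B", "": ""}[matrix.loc[p, q]]
                assert matrix.loc[q, p] == mirrored

    def test_matches_exhaustive_adjudication(self):
        matrix = build_payoff_matrix()
        for pb in VALID_PLAYS:
            for pa in VALID_PLAYS:
                total = pa.hand + pb.hand
                expect = ""
                if pb.call == total and pa.call != total:
                    expect = "B"
                elif pa.call == total and pb.call != total:
                    expect = "A"
                assert matrix.loc[pb.label(), pa.label()] == expect


class FlakyAgent:
    """Emits an invalid play every other call."""

    def __init__(self):
        self.count = 0

    def __call__(self, rng):
        self.count += 1
        if self.count % 2 == 1:
            return Play(1, 7)
        return Play(int(rng.integers(1, 6)), 6)


class TestSimulateMatch:
    def test_target_one_stops_at_first_scored_round(self):
        match = simulate_match(UniformRandomAgent(), UniformRandomAgent(), target_score=1, seed=3)
        assert max(match.scores.values()) == 1
        assert match.rounds[-1].winner is not None
        assert all(r.winner is None for r in match.rounds[:-1])

    def test_seed_makes_matches_identical(self):
        a = simulate_match(UniformRandomAgent(), UniformRandomAgent(), target_score=5, seed=11)
        b = simulate_match(UniformRandomAgent(), UniformRandomAgent(), target_score=5, seed=11)
        assert a == b

    def test_final_margin_leaves_exactly_one_side_at_target(self):
        match = simulate_match(UniformRandomAgent(), UniformRandomAgent(), target_score=10, seed=5)
        assert sorted(match.scores.values())[-1] == 10
        assert sum(v == 10 for v in match.scores.values()) == 1
        decided = sum(1 for r in match.rounds if r.winner is not None)
        assert decided == sum(match.scores.values())

    def test_team_substitution_on_scored_rounds_only(self):
        match = simulate_match(
            [UniformRandomAgent(), UniformRandomAgent()],
            [UniformRandomAgent(), UniformRandomAgent()],
            target_score=16,
            team_mode=True,
            seed=7,
        )
        for i in range(1, len(match.rounds)):
            prev_winner = match.rounds[i - 1].winner
            before, after = match.lineup_history[i - 1], match.lineup_history[i]
            if prev_winner is None:
                assert before == after
            else:
                keep = 0 if prev_winner == "A" else 1
                sub = 1 - keep
                assert before[keep] == after[keep]
                assert before[sub] != after[sub]

    def test_invalid_plays_are_resampled_and_counted(self):
        match = simulate_match(FlakyAgent(), UniformRandomAgent(), target_score=3, seed=1)
        assert match.invalid_play_resamples > 0
        assert all(r.play_a.is_valid and r.play_b.is_valid for r in match.rounds)

    def test_invalid_plays_can_abort(self):
        with pytest.raises(InvalidPlayError):
            simulate_match(FlakyAgent(), UniformRandomAgent(), target_score=3, seed=1,
                           on_invalid="abort")

    def test_markov_agents_play_full_match(self):
        agents = lambda: MarkovHandAgent(AgentConfig(), under_load=False)
        match = simulate_match(agents(), agents(), target_score=4, seed=2)
        assert max(match.scores.values()) == 4

    def test_round_win_rate_matches_payoff_matrix_expectation(self):
        # uniform agents put mass 1/25 on each valid play, so the per-round
        # B-win probability is the B-cell fraction of the 625-pair table
        matrix = build_payoff_matrix()
        expected = float((matrix == "B").sum().sum()) / matrix.size
        match = simulate_match(UniformRandomAgent(), UniformRandomAgent(),
                               target_score=2000, seed=13)
        rate = sum(r.winner == "B" for r in match.rounds) / len(match.rounds)
        assert rate == pytest.approx(expected, abs=0.012)


class TestHandSequenceExtraction:
    def test_one_vs_one_gives_two_full_length_sequences(self):
        match = simulate_match(UniformRandomAgent(), UniformRandomAgent(), target_score=5, seed=23)
        seqs = extract_hand_sequences(match)
        assert set(seqs) == {"A0", "B0"}
        assert all(s.n == len(match.rounds) for s in seqs.values())

    def test_team_sequence_lengths_sum_to_twice_the_rounds(self):
        match = simulate_match(
            [UniformRandomAgent(), UniformRandomAgent()],
            [UniformRandomAgent(), UniformRandomAgent()],
            target_score=16,
            team_mode=True,
            seed=29,
        )
        seqs = extract_hand_sequences(match)
        assert sum(s.n for s in seqs.values()) == 2 * len(match.rounds)

    def test_hand_built_substitution_record(self):
        # 6 rounds; side A substitutes after round 3, side B never does;
        # only the last round is scored (B calls the sum of 2)
        hands_a = (1, 2, 3, 4, 5, 1)
        calls_b = (6, 2, 2, 2, 2, 2)
        rounds = tuple(
            adjudicate_round(Play(h, h + 2), Play(1, cb))
            for h, cb in zip(hands_a, calls_b)
        )
        assert [r.winner for r in rounds] == [None] * 5 + ["B"]
        lineup = (("A0", "B0"),) * 3 + (("A1", "B0"),) * 3
        match = MatchRecord(rounds=rounds, lineup_history=lineup,
                            scores={"A": 0, "B": 1}, target_score=1, team_mode=True)
        seqs = extract_hand_sequences(match)
        assert sorted((pid, s.n) for pid, s in seqs.items()) == [
            ("A0", 3), ("A1", 3), ("B0", 6)]
        assert seqs["A0"].values == (1, 2, 3)
        assert seqs["A1"].values == (4, 5, 1)


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path):
        match = simulate_match(UniformRandomAgent(), UniformRandomAgent(), target_score=6, seed=31)
        write_match(match, tmp_path / "rounds.csv", tmp_path / "report.json")
        back = read_match(tmp_path / "rounds.csv", tmp_path / "report.json")
        assert back == match

    def test_frame_has_one_row_per_round(self):
        match = simulate_match(UniformRandomAgent(), UniformRandomAgent(), target_score=3, seed=37)
        frame = match_to_frame(match)
        assert len(frame) == len(match.rounds)
        assert (frame["sum"] == frame["hand_a"] + frame["hand_b"]).all()
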