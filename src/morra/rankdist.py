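"""Subjective-vs-actual frequency rank distance (declarative memory score).

After a match, a player ranks the five hand-numbers from the one they
believe they showed most to the one they believe they showed least.  The
same five numbers are also ranked by their observed frequency in the
transcribed sequence.  The discrepancy between the two rankings is the
Spearman footrule: for each number, the absolute difference between its
subjective and actual rank position, summed over the five numbers.  For
five items the maximum is 12; 0 means perfect declarative memory of one's
own play frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import pandas as pd

from .metrics import ResponseSequence, singlet_counts

__all__ = [
    "RankingPair",
    "actual_ranking_from_sequence",
    "footrule_distance",
    "max_footrule",
    "read_rankings",
    "rank_distance_report",
]


@dataclass(frozen=True)
class RankingPair:
    """Two rankings of the alphabet and the footrule distance between them.

    ``per_rank_distance[k]`` is the displacement of the item the player
    subjectively ranked (k+1)-th; ``percent_of_max`` rounds half-up to an
    integer percentage of the maximum possible distance.
    """

    subjective: tuple[int, ...]
    actual: tuple[int, ...]
    per_rank_distance: tuple[int, ...]
    total_distance: int
    percent_of_max: int
    tie_groups: tuple[tuple[int, ...], ...] = ()


def actual_ranking_from_sequence(seq: ResponseSequence):
    """Rank the alphabet by observed frequency, descending.

    Ties break by ascending face value and are reported as tie groups so
    callers can exclude ambiguous cases.  Returns ``(ranking, tie_groups)``.
    """
    if seq.n == 0:
        raise ValueError("cannot rank an empty sequence")
    counts = singlet_counts(seq)
    ranking = tuple(sorted(seq.alphabet, key=lambda s: (-counts[s], s)))
    groups: dict[int, list[int]] = {}
    for s in seq.alphabet:
        groups.setdefault(counts[s], []).append(s)
    ties = tuple(
        tuple(sorted(members))
        for count, members in sorted(groups.items(), reverse=True)
        if len(members) > 1
    )
    return ranking, ties


@lru_cache(maxsize=None)
def max_footrule(alphabet_size: int) -> int:
    """Maximum footrule distance between two rankings of that many items.

    By left-invariance the maximum can be found against the identity
    ranking; small sizes are brute-forced, larger ones use the reversal
    (which attains the maximum, floor(size^2 / 2))."""
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be >= 1")
    if alphabet_size <= 7:
        identity = tuple(range(alphabet_size))
        return max(
            sum(abs(p.index(x) - x) for x in identity)
            for p in permutations(identity)
        )
    return alphabet_size**2 // 2


def footrule_distance(subjective: Sequence[int], actual: Sequence[int]) -> RankingPair:
    """Spearman footrule between a subjective and an actual ranking.

    Both arguments are orderings from most to least frequent.  Each item's
    displacement is the absolute difference of its positions in the two
    rankings; ``per_rank_distance`` lists displacements in subjective-rank
    order and ``total_distance`` is their sum (always even).
    """
    subjective = tuple(subjective)
    actual = tuple(actual)
    if sorted(subjective) != sorted(actual) or len(set(subjective)) != len(subjective):
        raise ValueError("subjective and actual must be permutations of the same alphabet")
    pos_actual = {x: i for i, x in enumerate(actual)}
    per_rank = tuple(abs(i - pos_actual[x]) for i, x in enumerate(subjective))
    total = sum(per_rank)
    maximum = max_footrule(len(subjective))
    percent = 0 if maximum == 0 else math.floor(100 * total / maximum + 0.5)
    return RankingPair(
        subjective=subjective,
        actual=actual,
        per_rank_distance=per_rank,
        total_distance=total,
        percent_of_max=percent,
    )


def read_rankings(path) -> dict[str, dict[str, tuple[int, ...]]]:
    """Read a two-row-per-participant ranking table.

    Expected columns: ``participant_id, kind, r1..r5`` with ``kind`` in
    {subjective, actual}; ``r1`` is the (believed or observed) most
    frequent number.
    """
    frame = pd.read_csv(path, dtype={"participant_id": str})
    rank_cols = [c for c in frame.columns if c.startswith("r")]
    out: dict[str, dict[str, tuple[int, ...]]] = {}
    for row in frame.itertuples(index=False):
        kind = row.kind
        if kind not in ("subjective", "actual"):
            raise ValueError(f"unknown ranking kind {kind!r}")
        out.setdefault(row.participant_id, {})[kind] = tuple(
            int(getattr(row, c)) for c in rank_cols
        )
    for pid, kinds in out.items():
        missing = {"subjective", "actual"} - set(kinds)
        if missing:
            raise ValueError(f"participant {pid}: missing {sorted(missing)} ranking")
    return out


def rank_distance_report(rankings: dict[str, dict[str, tuple[int, ...]]]) -> pd.DataFrame:
    """Per-participant footrule report (per-rank distances, total, percent).

    The final row summarises with the mean total distance.
    """
    rows = []
    for pid in rankings:
        pair = footrule_distance(rankings[pid]["subjective"], rankings[pid]["actual"])
        k = len(pair.subjective)
        rows.append(
            {
                "participant_id": pid,
                **{f"subj_r{i+1}": pair.subjective[i] for i in range(k)},
                **{f"act_r{i+1}": pair.actual[i] for i in range(k)},
                **{f"dist_r{i+1}": pair.per_rank_distance[i] for i in range(k)},
                "total_distance": pair.total_distance,
                "percent_of_max": pair.percent_of_max,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame.attrs["mean_total_distance"] = float(frame["total_distance"].mean())
    return frame
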