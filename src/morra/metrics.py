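"""Randomness indices for bounded-alphabet response sequences.

Human attempts at producing "random" sequences over a small response set
(here, the hand-numbers 1-5 of a Morra player, or digits produced in a
paced random number generation task) deviate from an ideal uniform i.i.d.
source in characteristic ways: over-use of favourite responses, favoured
response pairs, missing pairs, slow cycling through the alternatives, and
atypical spacing between repeats.  This module computes the five classical
indices that quantify those deviations:

``redundancy``
    Percentage shortfall of the single-response entropy from its maximum
    (0% = equifrequent use of all alternatives, 100% = a single response).
``fpr_index``
    Frequency of paired responses (Evans' RNG index): the ratio of
    digram-count information to singlet-count information, in [0, 1];
    rises when particular adjacent pairs are favoured.
``nsq``
    Null-score quotient: the percentage of possible ordered digrams never
    produced, scaled to its maximum (a^2 - 1 for alphabet size a).
``coupon_score``
    Mean number of responses needed to cycle through all alternatives,
    measured on non-overlapping segments; the floor is a (=5 here), the
    i.i.d.-uniform expectation is a * H_a (~11.42 for a = 5).
``repetition_gap_mean``
    Mean positional distance between successive occurrences of the same
    response (adjacent repeat = 1); ~5 under uniform responding with five
    alternatives, lower when responses perseverate.

All logarithms are base 2.  Indices that cannot be computed on a given
sequence (e.g. the coupon score of a sequence that never completes a
cycle) raise :class:`UndefinedIndexError`; :func:`randomness_profile`
converts those into explicit NaN-plus-flag entries, never silent zeros.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "DEFAULT_ALPHABET",
    "GROUPS",
    "TASKS",
    "AlphabetError",
    "UndefinedIndexError",
    "ResponseSequence",
    "RandomnessProfile",
    "singlet_counts",
    "digram_counts",
    "redundancy",
    "fpr_index",
    "nsq",
    "coupon_score",
    "repetition_gap_mean",
    "randomness_profile",
    "INDEX_NAMES",
]

#: Hand-numbers a Morra player can show.
DEFAULT_ALPHABET: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Closed vocabularies for sequence metadata.
GROUPS = frozenset({"expert", "beginner"})
TASKS = frozenset({"morra", "rngt"})

#: Stable order of the five indices in profiles and reports.
INDEX_NAMES = ("redundancy", "fpr", "nsq", "coupon", "rep_gap")


class UndefinedIndexError(ValueError):
    """An index has no defined value on this sequence (e.g. empty input)."""


class AlphabetError(ValueError):
    """A sequence contains values outside its declared alphabet."""

    def __init__(self, message: str, positions: tuple[int, ...] = ()):
        super().__init__(message)
        self.positions = positions


@dataclass(frozen=True)
class ResponseSequence:
    """An ordered sequence of responses over a fixed small alphabet.

    Parameters
    ----------
    values
        The responses, in production order.
    alphabet
        The closed set of admissible responses (default: hand-numbers 1-5).
    participant_id, group, task
        Optional metadata.  ``group`` must be ``"expert"`` or ``"beginner"``
        and ``task`` must be ``"morra"`` or ``"rngt"`` when given.
    """

    values: tuple[int, ...]
    alphabet: tuple[int, ...] = DEFAULT_ALPHABET
    participant_id: str | None = None
    group: str | None = None
    task: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise ValueError("alphabet must be a non-empty set of distinct symbols")
        allowed = set(self.alphabet)
        bad = tuple(i for i, v in enumerate(self.values) if v not in allowed)
        if bad:
            raise AlphabetError(
                f"off-alphabet values at positions {bad[:10]}"
                f"{'...' if len(bad) > 10 else ''} (0-based)",
                positions=bad,
            )
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {sorted(GROUPS)}")
        if self.task is not None and self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {sorted(TASKS)}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def a(self) -> int:
        return len(self.alphabet)

    def truncated(self, length: int) -> "ResponseSequence":
        """First ``length`` responses, metadata preserved."""
        return ResponseSequence(
            self.values[:length],
            alphabet=self.alphabet,
            participant_id=self.participant_id,
            group=self.group,
            task=self.task,
        )


@dataclass(frozen=True)
class RandomnessProfile:
    """The five randomness indices of one sequence, plus their raw counts.

    Indices flagged in ``undefined`` hold ``nan``; ``singlet_counts`` and
    ``digram_counts`` always sum to n and n-1 respectively.
    """

    redundancy: float
    fpr: float
    nsq: float
    coupon: float
    rep_gap: float
    singlet_counts: Mapping[int, int]
    digram_counts: Mapping[tuple[int, int], int]
    n: int
    a: int
    participant_id: str | None = None
    group: str | None = None
    task: str | None = None
    undefined: frozenset[str] = field(default_factory=frozenset)

    def index_values(self) -> dict[str, float]:
        return {
            "redundancy": self.redundancy,
            "fpr": self.fpr,
            "nsq": self.nsq,
            "coupon": self.coupon,
            "rep_gap": self.rep_gap,
        }


def _require(seq: ResponseSequence, min_n: int, what: str) -> None:
    if seq.n < min_n:
        raise UndefinedIndexError(f"{what} undefined for a sequence of length {seq.n}")


def singlet_counts(seq: ResponseSequence) -> dict[int, int]:
    """Count of each alphabet symbol, zeros included."""
    c = Counter(seq.values)
    return {s: c.get(s, 0) for s in seq.alphabet}


def digram_counts(seq: ResponseSequence) -> dict[tuple[int, int], int]:
    """Count of each ordered adjacent pair, zeros included."""
    c = Counter(zip(seq.values, seq.values[1:]))
    return {(x, y): c.get((x, y), 0) for x in seq.alphabet for y in seq.alphabet}


def _nlogn(counts) -> float:
    # sum n_i * log2(n_i); terms with n_i <= 1 contribute zero
    return sum(c * math.log2(c) for c in counts if c > 1)


def redundancy(seq: ResponseSequence) -> float:
    """Redundancy R = 100 * (1 - H / H_max), a percentage in [0, 100].

    H is the single-response entropy ``log2(n) - (1/n) * sum_i n_i log2 n_i``
    and H_max = log2(a).  0% means all alternatives equifrequent, 100% means
    a single alternative was used throughout.
    """
    _require(seq, 1, "redundancy")
    n = seq.n
    h = math.log2(n) - _nlogn(singlet_counts(seq).values()) / n
    h_max = math.log2(seq.a)
    r = 100.0 * (1.0 - h / h_max)
    return min(100.0, max(0.0, r))  # clamp float dust at the exact bounds


def fpr_index(seq: ResponseSequence) -> float:
    """Frequency of paired responses (Evans' RNG index), in [0, 1].

    Ratio of digram-count information to singlet-count information:
    ``sum_ij n_ij log2 n_ij / sum_i n_i log2 n_i``.  Undefined when no
    single response repeats (zero denominator).
    """
    _require(seq, 2, "FPR")
    denom = _nlogn(singlet_counts(seq).values())
    if denom <= 0.0:
        raise UndefinedIndexError("FPR undefined: no response occurs more than once")
    return _nlogn(digram_counts(seq).values()) / denom


def nsq(seq: ResponseSequence) -> float:
    """Null-score quotient: percentage of possible digrams never produced.

    NS counts the ordered digrams (of the a^2 possible) absent from the
    sequence; NSQ = 100 * NS / (a^2 - 1), so a constant sequence - which
    realises exactly one digram - scores 100%.
    """
    _require(seq, 2, "NSQ")
    observed = len(set(zip(seq.values, seq.values[1:])))
    ns = seq.a**2 - observed
    return 100.0 * ns / (seq.a**2 - 1)


def coupon_score(seq: ResponseSequence) -> float:
    """Mean responses per completed cycle through all alternatives.

    Scans left to right in non-overlapping segments: a segment ends at the
    position where every alternative has appeared since the segment start,
    and the next segment starts fresh.  An incomplete trailing segment is
    discarded.  The floor is a (perfect cycling); undefined when no segment
    completes.
    """
    lengths: list[int] = []
    seen: set[int] = set()
    start = 0
    for i, v in enumerate(seq.values):
        seen.add(v)
        if len(seen) == seq.a:
            lengths.append(i - start + 1)
            seen.clear()
            start = i + 1
    if not lengths:
        raise UndefinedIndexError("coupon score undefined: no complete cycle through all alternatives")
    return sum(lengths) / len(lengths)


def repetition_gap_mean(seq: ResponseSequence) -> float:
    """Mean positional distance between successive occurrences of a value.

    Every occurrence of a value seen before contributes the distance to its
    immediately previous occurrence (adjacent repeat = 1); the index is the
    mean over all such recurrences.  Undefined when nothing recurs.
    """
    last: dict[int, int] = {}
    gaps: list[int] = []
    for i, v in enumerate(seq.values):
        if v in last:
            gaps.append(i - last[v])
        last[v] = i
    if not gaps:
        raise UndefinedIndexError("repetition gap undefined: no value recurs")
    return sum(gaps) / len(gaps)


def randomness_profile(seq: ResponseSequence) -> RandomnessProfile:
    """Bundle the five indices with their counts and undefined-index flags.

    Indices whose preconditions fail are reported as NaN and named in
    ``undefined`` rather than silently set to zero or a bound.
    """
    _require(seq, 2, "randomness profile")
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for name, fn in (
        ("redundancy", redundancy),
        ("fpr", fpr_index),
        ("nsq", nsq),
        ("coupon", coupon_score),
        ("rep_gap", repetition_gap_mean),
    ):
        try:
            values[name] = fn(seq)
        except UndefinedIndexError:
            values[name] = math.nan
            undefined.add(name)
    return RandomnessProfile(
        redundancy=values["redundancy"],
        fpr=values["fpr"],
        nsq=values["nsq"],
        coupon=values["coupon"],
        rep_gap=values["rep_gap"],
        singlet_counts=singlet_counts(seq),
        digram_counts=digram_counts(seq),
        n=seq.n,
        a=seq.a,
        participant_id=seq.participant_id,
        group=seq.group,
        task=seq.task,
        undefined=frozenset(undefined),
    )
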