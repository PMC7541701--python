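"""Reading, standardizing and writing response-sequence tables.

Recorded sequences vary in length (games differ in length, and team play
splits rounds across teammates), so before index computation every
sequence is standardized: sequences of at least the standard length
(default 57 responses) are truncated to their first 57 values, shorter
ones are excluded with an explicit reason.  Exclusion is a recorded
outcome, never a silent drop.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .metrics import (
    DEFAULT_ALPHABET,
    GROUPS,
    INDEX_NAMES,
    TASKS,
    RandomnessProfile,
    ResponseSequence,
)

__all__ = [
    "SequenceSet",
    "SequenceInputError",
    "read_sequences",
    "write_sequences",
    "standardize",
    "profiles_frame",
    "write_profiles",
    "read_profiles",
]

STANDARD_LENGTH = 57
REASON_TOO_SHORT = "below minimum length"

#: Stable column order of profile tables.
PROFILE_COLUMNS = ["participant_id", "group", "task", "n"] + list(INDEX_NAMES) + ["flags"]


class SequenceInputError(ValueError):
    """Malformed sequence table (bad label, gap in positions, off-alphabet value)."""


@dataclass(frozen=True)
class SequenceSet:
    """A collection of response sequences plus its filtering provenance."""

    sequences: tuple[ResponseSequence, ...]
    provenance: dict = field(default_factory=dict)
    excluded: tuple[tuple[str, int, str], ...] = ()

    def __len__(self) -> int:
        return len(self.sequences)

    def keys(self) -> list[tuple[str | None, str | None, str | None]]:
        return [(s.participant_id, s.group, s.task) for s in self.sequences]


def _sniff_sep(path) -> str:
    sample = Path(path).read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_sequences(path, alphabet: Sequence[int] = DEFAULT_ALPHABET) -> SequenceSet:
    """Read an unstandardized sequence table (long or wide form).

    Long form has columns ``participant_id, group, task, position, value``
    (positions 1-based and contiguous per sequence); wide form has
    ``participant_id, group, task, v1..vK`` with trailing blanks allowed
    for shorter sequences.  The delimiter (comma or tab) is sniffed from
    the header.  Group/task labels are validated against the closed
    vocabularies; violations report the offending 1-based file row.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    cols = list(frame.columns)
    for required in ("participant_id", "group", "task"):
        if required not in cols:
            raise SequenceInputError(f"missing required column {required!r}")
    long_form = "position" in cols and "value" in cols
    allowed = set(alphabet)

    def check_labels(row_no: int, group: str, task: str) -> None:
        if group not in GROUPS:
            raise SequenceInputError(f"row {row_no}: unknown group {group!r}")
        if task not in TASKS:
            raise SequenceInputError(f"row {row_no}: unknown task {task!r}")

    sequences: list[ResponseSequence] = []
    if long_form:
        by_key: dict[tuple[str, str, str], list[tuple[int, int, int]]] = {}
        for i, row in enumerate(frame.itertuples(index=False)):
            row_no = i + 2  # 1-based, after the header line
            check_labels(row_no, row.group, row.task)
            value = int(row.value)
            if value not in allowed:
                raise SequenceInputError(f"row {row_no}: value {value} outside alphabet {sorted(allowed)}")
            by_key.setdefault((row.participant_id, row.group, row.task), []).append(
                (int(row.position), value, row_no)
            )
        for (pid, group, task), entries in by_key.items():
            entries.sort()
            positions = [p for p, _, _ in entries]
            if positions != list(range(1, len(positions) + 1)):
                bad = next(
                    (rn for k, (p, _, rn) in enumerate(entries) if p != k + 1),
                    entries[0][2],
                )
                raise SequenceInputError(
                    f"row {bad}: non-contiguous positions for sequence {pid}/{group}/{task}"
                )
            sequences.append(
                ResponseSequence(
                    tuple(v for _, v, _ in entries),
                    alphabet=tuple(alphabet),
                    participant_id=pid,
                    group=group,
                    task=task,
                )
            )
    else:
        value_cols = [c for c in cols if c not in ("participant_id", "group", "task")]
        if not value_cols:
            raise SequenceInputError("wide-form file has no value columns (v1..vK)")
        for i, row in enumerate(frame.itertuples(index=False)):
            row_no = i + 2
            check_labels(row_no, row.group, row.task)
            values = []
            ended = False
            for c in value_cols:
                raw = getattr(row, c)
                if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                    ended = True
                    continue
                if ended:
                    raise SequenceInputError(
                        f"row {row_no}: gap in wide-form values for {row.participant_id}"
                    )
                v = int(raw)
                if v not in allowed:
                    raise SequenceInputError(
                        f"row {row_no}: value {v} outside alphabet {sorted(allowed)}"
                    )
                values.append(v)
            sequences.append(
                ResponseSequence(
                    tuple(values),
                    alphabet=tuple(alphabet),
                    participant_id=row.participant_id,
                    group=row.group,
                    task=row.task,
                )
            )
    return SequenceSet(
        sequences=tuple(sequences),
        provenance={"source": str(path), "dialect": "long" if long_form else "wide", "sep": sep},
    )


def write_sequences(sset: SequenceSet, path, sep: str = ",") -> None:
    """Write a SequenceSet in long form (the format read_sequences reads)."""
    rows = [
        {
            "participant_id": s.participant_id,
            "group": s.group,
            "task": s.task,
            "position": i + 1,
            "value": v,
        }
        for s in sset.sequences
        for i, v in enumerate(s.values)
    ]
    pd.DataFrame(rows, columns=["participant_id", "group", "task", "position", "value"]).to_csv(
        path, index=False, sep=sep
    )


def standardize(sset: SequenceSet, standard_length: int = STANDARD_LENGTH) -> SequenceSet:
    """Truncate to the first ``standard_length`` responses; exclude shorter.

    Idempotent, and every dropped sequence is accounted for in
    ``excluded`` as ``(participant/group/task key, original length,
    reason)``.
    """
    if sset.sequences and standard_length < max(s.a for s in sset.sequences):
        raise ValueError("standard_length must be at least the alphabet size")
    kept: list[ResponseSequence] = []
    excluded = list(sset.excluded)
    for s in sset.sequences:
        if s.n >= standard_length:
            kept.append(s.truncated(standard_length))
        else:
            key = "/".join(str(x) for x in (s.participant_id, s.group, s.task))
            excluded.append((key, s.n, REASON_TOO_SHORT))
    provenance = dict(sset.provenance)
    provenance["standard_length"] = standard_length
    return SequenceSet(sequences=tuple(kept), provenance=provenance, excluded=tuple(excluded))


def profiles_frame(profiles: Iterable[RandomnessProfile]) -> pd.DataFrame:
    """Tabulate profiles with the stable column order."""
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.participant_id,
            "group": p.group,
            "task": p.task,
            "n": p.n,
            **p.index_values(),
            "flags": ";".join(sorted(p.undefined)),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profiles(
    sset: SequenceSet,
    profiles: Sequence[RandomnessProfile],
    path,
    exclusions_path=None,
) -> None:
    """Write one profile row per retained sequence plus an exclusion report.

    Profiles must match the retained sequences one-to-one (same ids in the
    same order); the exclusion sidecar (default: ``<path>.exclusions.csv``)
    echoes every dropped sequence.
    """
    ids_set = [(s.participant_id, s.group, s.task) for s in sset.sequences]
    ids_prof = [(p.participant_id, p.group, p.task) for p in profiles]
    if ids_set != ids_prof:
        raise ValueError("profiles do not match the retained sequences one-to-one")
    frame = profiles_frame(profiles)
    frame.to_csv(path, index=False, float_format="%.10g")
    if exclusions_path is None:
        exclusions_path = str(path) + ".exclusions.csv"
    pd.DataFrame(list(sset.excluded), columns=["id", "length", "reason"]).to_csv(
        exclusions_path, index=False
    )


def read_profiles(path) -> pd.DataFrame:
    """Read back a profile table written by :func:`write_profiles`."""
    return pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False, na_values=[""])
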