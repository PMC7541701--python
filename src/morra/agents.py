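"""Synthetic response-sequence generators (first-order Markov agents).

The recorded sequences behind the expert/beginner Morra study are not
publicly deposited, so analyses here run on synthetic sequences with the
statistical structure the randomness indices are sensitive to.  A
first-order Markov family is the minimal generative model that can move
all five indices: a zeroth-order preference weight vector shifts the
redundancy index, while the first-order repetition term shifts the paired
response (FPR), null-score, coupon and repetition-gap indices.

Each agent is parameterised by

``w``
    per-symbol preference weights (favourite-number bias),
``mu``
    a repetition multiplier on the previous response (>1 perseveration,
    <1 repetition avoidance, 1 neutral),
``lambda_load``
    a load exponent: under concurrent game load every weight is raised to
    the power ``1 + lambda_load``, sharpening both the favourite-number
    bias and the perseveration at once.  ``lambda_load = 0`` (or load off)
    leaves the base model untouched.

With uniform ``w``, ``mu = 1`` and no load the generator is i.i.d. uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .metrics import DEFAULT_ALPHABET, ResponseSequence
from .preprocessing import SequenceSet, standardize

__all__ = [
    "AgentConfig",
    "StudyDesign",
    "default_configs",
    "generate_sequence",
    "generate_study",
]


@dataclass(frozen=True)
class AgentConfig:
    """Generative parameters of one synthetic player population."""

    w: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    mu: float = 1.0
    lambda_load: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", tuple(float(x) for x in self.w))
        if not self.w or any(x <= 0 for x in self.w):
            raise ValueError("all preference weights must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.lambda_load < 0:
            raise ValueError("lambda_load must be >= 0")


def default_configs() -> dict[str, AgentConfig]:
    """Documented default agent populations for the two expertise groups.

    Experts are nearly uniform with mild repetition avoidance and almost no
    load sensitivity (their sequence quality barely changes between tasks);
    beginners carry a favourite-number gradient, perseverate, and degrade
    strongly under game load.  These are calibration constants of the
    synthetic study, not fitted quantities.
    """
    return {
        "expert": AgentConfig(w=(1.0, 1.0, 1.0, 1.0, 1.0), mu=0.9, lambda_load=0.1, label="expert"),
        "beginner": AgentConfig(w=(1.5, 1.2, 1.0, 0.9, 0.7), mu=1.8, lambda_load=1.0, label="beginner"),
    }


def _step(config: AgentConfig, under_load: bool, prev: int | None, rng: np.random.Generator) -> int:
    """Draw one response (1-based symbol index order of DEFAULT_ALPHABET)."""
    lam = config.lambda_load if under_load else 0.0
    w = np.asarray(config.w, dtype=float) ** (1.0 + lam)
    if prev is not None:
        w = w.copy()
        w[prev - 1] *= config.mu ** (1.0 + lam)
    p = w / w.sum()
    return int(rng.choice(len(w), p=p)) + 1


def generate_sequence(
    config: AgentConfig,
    under_load: bool,
    length: int,
    seed: int | np.random.Generator,
    participant_id: str | None = None,
    group: str | None = None,
    task: str | None = None,
) -> ResponseSequence:
    """Sample one response sequence from the Markov agent model.

    The first response has probability proportional to ``w_j^(1+lam)``;
    each subsequent response additionally multiplies the weight of the
    previous symbol by ``mu^(1+lam)``, where ``lam = lambda_load`` under
    load and 0 otherwise.  Deterministic given the seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = config.lambda_load if under_load else 0.0
    w = np.asarray(config.w, dtype=float) ** (1.0 + lam)
    a = len(w)
    rep = config.mu ** (1.0 + lam)

    # Precompute the a+1 cumulative distributions (no previous symbol, or
    # previous symbol = j) and walk the chain against one block of uniforms.
    cum = np.empty((a + 1, a))
    cum[0] = np.cumsum(w / w.sum())
    for j in range(a):
        wj = w.copy()
        wj[j] *= rep
        cum[j + 1] = np.cumsum(wj / wj.sum())
    u = rng.random(length)
    out = np.empty(length, dtype=int)
    prev = 0
    for i in range(length):
        k = int(np.searchsorted(cum[prev], u[i], side="right"))
        k = min(k, a - 1)
        out[i] = k + 1
        prev = k + 1
    return ResponseSequence(
        tuple(int(v) for v in out),
        alphabet=DEFAULT_ALPHABET[:a] if a <= len(DEFAULT_ALPHABET) else tuple(range(1, a + 1)),
        participant_id=participant_id,
        group=group,
        task=task,
    )


@dataclass(frozen=True)
class StudyDesign:
    """A 2 (expertise, between) x 2 (task, within) synthetic study.

    Defaults mirror the reference design: 9 experts and 9 beginners, each
    producing one in-game (Morra, under load) sequence of 57 responses and
    one isolated random-generation (RNGT, no load) sequence of 100
    responses that is subsequently standardized to the first 57.
    """

    n_per_group: int = 9
    groups: tuple[str, ...] = ("expert", "beginner")
    tasks: tuple[str, ...] = ("morra", "rngt")
    sequence_length: int = 57
    rngt_length: int = 100
    seed: int = 0
    configs: Mapping[str, AgentConfig] = field(default_factory=default_configs)


def generate_study(design: StudyDesign) -> SequenceSet:
    """Generate a full synthetic study, standardized to the design length.

    Each participant gets an independent child seed derived from the master
    seed, so studies are reproducible and participants are exchangeable
    across designs with the same seed.  Morra sequences are generated under
    load at the standard length; RNGT sequences are generated load-free at
    ``rngt_length`` and truncated to the standard length by the same
    preprocessing step the recorded pipeline uses.
    """
    ss = np.random.SeedSequence(design.seed)
    sequences = []
    pid = 0
    for group in design.groups:
        config = design.configs[group]
        for _ in range(design.n_per_group):
            participant = f"{group[0]}{pid:02d}"
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            for task in design.tasks:
                under_load = task == "morra"
                length = design.sequence_length if task == "morra" else design.rngt_length
                sequences.append(
                    generate_sequence(
                        config,
                        under_load=under_load,
                        length=length,
                        seed=rng,
                        participant_id=participant,
                        group=group,
                        task=task,
                    )
                )
            pid += 1
    raw = SequenceSet(
        sequences=tuple(sequences),
        provenance={
            "source": "synthetic",
            "seed": design.seed,
            "n_per_group": design.n_per_group,
            "configs": {g: vars(c) | {"w": list(c.w)} for g, c in design.configs.items()},
        },
    )
    return standardize(raw, standard_length=design.sequence_length)
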