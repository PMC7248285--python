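"""Stimulus grid enumeration and balanced trial schedules.

The emotion-categorisation task presents morphed anger/fear faces with direct
or averted gaze.  Each face identity contributes ``n_levels`` morph steps per
emotion per gaze direction plus two pure-neutral faces (direct and averted
gaze): ``4 * n_levels + 2`` stimuli per identity, 30 at the default 7 levels.
With 20 identities the full grid is 600 stimuli, presented once each across 5
blocks of 120 trials, every block exactly balanced for emotion, gaze, identity
gender and morph level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

EMOTIONS = ("anger", "fear", "neutral")
GAZES = ("direct", "averted")
GENDERS = ("female", "male")

SCHEDULE_COLUMNS = [
    "block",
    "trial_index",
    "identity_id",
    "gender",
    "emotion",
    "morph_level",
    "gaze",
]


class BalanceError(ValueError):
    """Raised when an exactly balanced block assignment is impossible."""


@dataclass(frozen=True)
class StimulusCondition:
    """One face stimulus, symbolically.

    ``morph_level`` is 1..n_levels from weakest to strongest emotion and 0 if
    and only if the emotion is neutral.
    """

    identity_id: int
    gender: str
    emotion: str
    morph_level: int
    gaze: str

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if self.gaze not in GAZES:
            raise ValueError(f"unknown gaze {self.gaze!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if (self.emotion == "neutral") != (self.morph_level == 0):
            raise ValueError(
                "morph_level must be 0 if and only if emotion is neutral; "
                f"got emotion={self.emotion!r}, morph_level={self.morph_level}"
            )
        if self.morph_level < 0:
            raise ValueError("morph_level must be non-negative")


def identity_gender(identity_id: int, n_identities: int) -> str:
    """Gender of an identity under the default half/half split.

    Identities 1..ceil(n/2) are female, the rest male, so an odd count puts
    the extra identity in the female stratum.
    """
    n_female = (n_identities + 1) // 2
    return "female" if identity_id <= n_female else "male"


def enumerate_stimuli(n_identities: int, n_levels: int = 7) -> list[StimulusCondition]:
    """Enumerate the full stimulus grid.

    Returns ``n_identities * (4 * n_levels + 2)`` unique conditions: every
    emotion x morph-level x gaze combination plus the two neutral faces per
    identity.

    Parameters
    ----------
    n_identities:
        Number of face identities (>= 0); genders split half/half.
    n_levels:
        Number of morph steps per emotion continuum (>= 1).
    """
    if n_identities < 0:
        raise ValueError("n_identities must be >= 0")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")

    grid: list[StimulusCondition] = []
    for ident in range(1, n_identities + 1):
        gender = identity_gender(ident, n_identities)
        for gaze in GAZES:
            for emotion in ("anger", "fear"):
                for level in range(1, n_levels + 1):
                    grid.append(
                        StimulusCondition(ident, gender, emotion, level, gaze)
                    )
            grid.append(StimulusCondition(ident, gender, "neutral", 0, gaze))
    return grid


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered presentation schedule over a stimulus grid.

    ``trials`` holds one row per trial with a 1-based ``block`` index and a
    0-based global ``trial_index``; every stimulus of the grid appears exactly
    once.  ``response_mapping`` records which hand answers "anger" (metadata
    only; it never enters the modelling).
    """

    trials: pd.DataFrame
    response_mapping: dict[str, str]
    seed: int

    @property
    def n_blocks(self) -> int:
        return int(self.trials["block"].max())

    def __len__(self) -> int:
        return len(self.trials)

    def to_csv(self, path, subject: str | int | None = None) -> None:
        out = self.trials.copy()
        if subject is not None:
            out.insert(0, "subject", subject)
        out.to_csv(path, index=False)


def response_mapping(subject_index: int) -> dict[str, str]:
    """Counterbalanced anger/fear hand mapping, alternating by subject parity."""
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    if subject_index % 2 == 0:
        return {"anger": "left", "fear": "right"}
    return {"anger": "right", "fear": "left"}


def _stratum_key(s: StimulusCondition) -> tuple:
    return (s.emotion, s.morph_level, s.gaze, s.gender)


def build_schedule(
    stimuli: Sequence[StimulusCondition],
    n_blocks: int,
    seed: int,
    subject_index: int = 0,
) -> TrialSchedule:
    """Assign stimuli to equally sized, exactly balanced blocks.

    Stimuli are stratified by the joint emotion x morph-level x gaze x gender
    combination; each stratum is shuffled and dealt round-robin to blocks, so
    every marginal factor count is identical across blocks.  Trial order
    within each block is then shuffled.  The same inputs and seed always give
    the same schedule.

    Raises
    ------
    BalanceError
        If the stimulus count or any joint stratum count is not divisible by
        ``n_blocks`` (exact balance would be impossible).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    n = len(stimuli)
    if n % n_blocks != 0:
        raise BalanceError(
            f"{n} stimuli cannot form {n_blocks} equal blocks"
        )

    strata: dict[tuple, list[StimulusCondition]] = {}
    for s in stimuli:
        strata.setdefault(_stratum_key(s), []).append(s)
    for key, members in strata.items():
        if len(members) % n_blocks != 0:
            raise BalanceError(
                f"stratum {key} has {len(members)} stimuli, not divisible by "
                f"{n_blocks} blocks; exact balance is infeasible"
            )

    rng = np.random.default_rng(seed)
    blocks: list[list[StimulusCondition]] = [[] for _ in range(n_blocks)]
    # Sort strata for a deterministic dealing order independent of input order.
    for key in sorted(strata):
        members = list(strata[key])
        rng.shuffle(members)
        per_block = len(members) // n_blocks
        for b in range(n_blocks):
            blocks[b].extend(members[b * per_block : (b + 1) * per_block])

    rows = []
    trial_index = 0
    for b, block in enumerate(blocks, start=1):
        order = rng.permutation(len(block))
        for i in order:
            s = block[i]
            rows.append(
                (b, trial_index, s.identity_id, s.gender, s.emotion,
                 s.morph_level, s.gaze)
            )
            trial_index += 1

    trials = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    return TrialSchedule(
        trials=trials,
        response_mapping=response_mapping(subject_index),
        seed=seed,
    )


def read_schedule_csv(path) -> pd.DataFrame:
    """Read a schedule table written by :meth:`TrialSchedule.to_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schedule file missing columns: {missing}")
    return df
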