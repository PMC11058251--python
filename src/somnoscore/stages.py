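"""Sleep-stage vocabulary and annotation-label mapping.

AASM scoring uses five stages (W, N1, N2, N3, REM).  Source hypnograms in the
R&K dialect additionally carry stage 4 (merged into N3 under AASM), movement
time ("M") and unscored ("?") epochs.  Movement/unscored epochs are carried
through the pipeline but masked out of training targets and evaluation.
"""

from __future__ import annotations

from enum import Enum


class StageLabel(Enum):
    """A 30-s epoch's sleep-stage annotation."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4
    MOVEMENT = 5
    UNKNOWN = 6

    @property
    def is_scoreable(self) -> bool:
        """True for the five AASM stages used as classifier targets."""
        return self.value < 5

    @property
    def is_sleep(self) -> bool:
        """True for N1/N2/N3/REM (used to delimit the in-bed period)."""
        return self in (StageLabel.N1, StageLabel.N2, StageLabel.N3, StageLabel.REM)


#: The five classifier classes, in canonical index order.
SCOREABLE_STAGES: tuple[StageLabel, ...] = (
    StageLabel.W,
    StageLabel.N1,
    StageLabel.N2,
    StageLabel.N3,
    StageLabel.REM,
)

STAGE_NAMES: tuple[str, ...] = tuple(s.name for s in SCOREABLE_STAGES)

# Sleep-EDF SC annotation alphabet (R&K): stages 3 and 4 merge into N3 under
# the AASM rules; "M" is movement time and "?" an unscored epoch.
_RK_TO_AASM: dict[str, StageLabel] = {
    "W": StageLabel.W,
    "1": StageLabel.N1,
    "2": StageLabel.N2,
    "3": StageLabel.N3,
    "4": StageLabel.N3,
    "R": StageLabel.REM,
    "M": StageLabel.MOVEMENT,
    "?": StageLabel.UNKNOWN,
}

# Aliases seen in EDF+ annotation tracks ("Sleep stage W") and AASM-style
# hypnogram exports; all normalize through the same table.
_ALIASES: dict[str, str] = {
    "SLEEP STAGE W": "W",
    "SLEEP STAGE 1": "1",
    "SLEEP STAGE 2": "2",
    "SLEEP STAGE 3": "3",
    "SLEEP STAGE 4": "4",
    "SLEEP STAGE R": "R",
    "SLEEP STAGE ?": "?",
    "MOVEMENT TIME": "M",
    "N1": "1",
    "N2": "2",
    "N3": "3",
    "N4": "4",
    "REM": "R",
}


class UnknownStageTokenError(ValueError):
    """Raised when a hypnogram token is outside the declared alphabet."""


def map_rk_to_aasm(raw: str) -> StageLabel:
    """Map one R&K / Sleep-EDF hypnogram token to an AASM :class:`StageLabel`.

    Stages "3" and "4" both map to N3 (the AASM merge); "M" and "?" map to
    MOVEMENT and UNKNOWN.  Raises :class:`UnknownStageTokenError` for tokens
    outside the alphabet, naming the offending token.
    """
    token = raw.strip()
    token = _ALIASES.get(token.upper(), token)
    try:
        return _RK_TO_AASM[token if token in _RK_TO_AASM else token.upper()]
    except KeyError:
        raise UnknownStageTokenError(f"unknown sleep-stage token: {raw!r}") from None
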