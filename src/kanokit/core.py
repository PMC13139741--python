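"""Core Kano-model vocabulary and the pair-level evaluation table.

The Kano method asks every respondent two questions per feature: a
*functional* question ("if this feature were available, how would you
feel?") and a *dysfunctional* one ("if it were NOT available?"), each
answered on the same 5-point scale.  The pair of answers indexes a fixed
5x5 evaluation table whose cells carry one of six categories:

=====  =================  ==============================================
tag    name               meaning
=====  =================  ==============================================
M      must-be            absence hurts, presence is taken for granted
O      one-dimensional    satisfaction tracks fulfilment linearly
A      attractive         unexpected delighter
I      indifferent        presence or absence barely matters
R      reverse            the respondent prefers the feature absent
Q      questionable       internally contradictory answer pair
=====  =================  ==============================================

The table is stored as a literal 5x5 grid constant so it can be printed,
documented and diff-tested cell by cell, rather than hidden in nested
conditionals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping


class KanoError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(KanoError, ValueError):
    """Malformed input: bad Likert code, bad weights, bad table shape."""


class NoDataError(KanoError, ValueError):
    """An operation received no usable observations."""


class UndefinedIndexError(KanoError, ZeroDivisionError):
    """SI/DSI requested for an item with A+O+M+I = 0."""


class UndefinedReliabilityError(KanoError, ZeroDivisionError):
    """Reliability statistic is undefined for this input (zero variance)."""


class LikertLevel(enum.IntEnum):
    """5-point answer scale used for both question forms.

    The coding direction is fixed: 1 = "I like it that way" through
    5 = "I dislike it that way".  Readers that ingest differently coded
    files must remap via the codebook; the core never guesses.
    """

    LIKE = 1
    MUST_BE = 2
    NEUTRAL = 3
    LIVE_WITH = 4
    DISLIKE = 5

    @property
    def label(self) -> str:
        return _LIKERT_LABELS[self]

    @classmethod
    def from_code(cls, code: object) -> "LikertLevel":
        """Coerce an integer-like code in 1..5, rejecting anything else."""
        try:
            value = int(code)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ValidationError(f"Likert code must be an integer 1-5, got {code!r}")
        if isinstance(code, float) and not float(code).is_integer():
            raise ValidationError(f"Likert code must be an integer 1-5, got {code!r}")
        if not 1 <= value <= 5:
            raise ValidationError(f"Likert code must be in 1-5, got {value}")
        return cls(value)


_LIKERT_LABELS: Mapping[LikertLevel, str] = {
    LikertLevel.LIKE: "like",
    LikertLevel.MUST_BE: "must-be",
    LikertLevel.NEUTRAL: "neutral",
    LikertLevel.LIVE_WITH: "live-with",
    LikertLevel.DISLIKE: "dislike",
}


class KanoCategory(enum.Enum):
    """The six Kano categories, keyed by their one-letter tag."""

    MUST_BE = "M"
    ONE_DIMENSIONAL = "O"
    ATTRACTIVE = "A"
    INDIFFERENT = "I"
    REVERSE = "R"
    QUESTIONABLE = "Q"

    @property
    def tag(self) -> str:
        return self.value

    @property
    def category_name(self) -> str:
        return self.name.lower().replace("_", "-")

    @classmethod
    def from_tag(cls, tag: str) -> "KanoCategory":
        try:
            return cls(tag.strip().upper())
        except ValueError:
            raise ValidationError(f"unknown Kano category tag {tag!r}")


#: Canonical category order used everywhere counts are displayed, and the
#: tie-break precedence for modal classification (see aggregate.py).
CATEGORY_ORDER: tuple[KanoCategory, ...] = (
    KanoCategory.MUST_BE,
    KanoCategory.ONE_DIMENSIONAL,
    KanoCategory.ATTRACTIVE,
    KanoCategory.INDIFFERENT,
    KanoCategory.REVERSE,
    KanoCategory.QUESTIONABLE,
)


@dataclass(frozen=True)
class ResponsePair:
    """One respondent's functional + dysfunctional answers for one item.

    Both sides must be present; incomplete pairs are dropped upstream
    (see :mod:`kanokit.io`), never silently imputed here.
    """

    functional: LikertLevel
    dysfunctional: LikertLevel

    def __post_init__(self) -> None:
        object.__setattr__(self, "functional", LikertLevel.from_code(self.functional))
        object.__setattr__(
            self, "dysfunctional", LikertLevel.from_code(self.dysfunctional)
        )


# The evaluation table: rows = functional answer 1..5, columns =
# dysfunctional answer 1..5.  Category multiset over the 25 cells:
# {Q:2, A:3, O:1, R:7, I:9, M:3}.
_GRID: tuple[tuple[str, ...], ...] = (
    #  dysfunctional:  like  must-be  neutral  live-with  dislike
    ("Q", "A", "A", "A", "O"),  # functional: like
    ("R", "I", "I", "I", "M"),  # functional: must-be
    ("R", "I", "I", "I", "M"),  # functional: neutral
    ("R", "I", "I", "I", "M"),  # functional: live-with
    ("R", "R", "R", "R", "Q"),  # functional: dislike
)


def evaluation_table() -> dict[tuple[LikertLevel, LikertLevel], KanoCategory]:
    """Full 25-cell lookup from (functional, dysfunctional) to category."""
    return {
        (f, d): KanoCategory(_GRID[f - 1][d - 1])
        for f in LikertLevel
        for d in LikertLevel
    }


def classify_pair(pair: ResponsePair) -> KanoCategory:
    """Classify one answer pair via the evaluation table.

    Total over all 25 cells; raises :class:`ValidationError` only if the
    pair itself carries an invalid Likert code (impossible for a
    well-constructed :class:`ResponsePair`).
    """
    return KanoCategory(_GRID[pair.functional - 1][pair.dysfunctional - 1])
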