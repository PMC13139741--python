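"""Satisfaction/importance coefficients and the strategy-quadrant matrix.

For an item with category counts A, O, M, I (reverse and questionable
answers are dropped from the denominator):

    SI  =  (A + O) / (A + O + M + I)          in [0, 1]
    DSI = -(O + M) / (A + O + M + I)          in [-1, 0]

SI (the "better" coefficient) is the fraction of classifiable
respondents whose satisfaction would rise if the feature were present;
|DSI| (the "worse" coefficient) is the fraction whose satisfaction would
fall if it were absent, signed negative by convention.

Each item is then plotted at (|DSI|, SI) and the plane is split at the
per-axis means into four strategy quadrants:

    I   predominance        high importance, high satisfaction
    II  improving           low importance, high satisfaction
    III secondary improving low importance, low satisfaction
    IV  reserving           high importance, low satisfaction

Boundary ties go to the high-importance / high-satisfaction side (>=).
Indices are computed at full precision; rounding (half away from zero,
2 decimals by default) happens only at the display layer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .aggregate import ItemClassification, ItemFrequencies, modal_category
from .core import KanoCategory, NoDataError, UndefinedIndexError

_M = KanoCategory.MUST_BE
_O = KanoCategory.ONE_DIMENSIONAL
_A = KanoCategory.ATTRACTIVE
_I = KanoCategory.INDIFFERENT


class Quadrant(enum.Enum):
    """Strategy quadrant of the importance-satisfaction matrix."""

    I = "predominance"
    II = "improving"
    III = "secondary improving"
    IV = "reserving"

    @property
    def strategy_name(self) -> str:
        return self.value


@dataclass(frozen=True)
class MatrixOrigin:
    """Crosshair splitting the (|DSI|, SI) plane: per-axis means."""

    x0: float  # mean |DSI| over items
    y0: float  # mean SI over items

    def __post_init__(self) -> None:
        if not (0.0 <= self.x0 <= 1.0 and 0.0 <= self.y0 <= 1.0):
            raise ValueError(f"origin out of range: ({self.x0}, {self.y0})")


@dataclass(frozen=True)
class ItemResult:
    """Everything the analysis knows about one item."""

    item_id: str
    frequencies: ItemFrequencies
    classification: ItemClassification
    si: float
    dsi: float
    quadrant: Quadrant | None = None

    @property
    def label(self) -> str:
        return self.frequencies.label

    @property
    def category(self) -> KanoCategory:
        return self.classification.category


def _classifiable(freqs: ItemFrequencies) -> int:
    return sum(freqs.count(c) for c in (_A, _O, _M, _I))


def satisfaction_index(freqs: ItemFrequencies) -> float:
    """SI = (A+O)/(A+O+M+I); R and Q counts are ignored."""
    denom = _classifiable(freqs)
    if denom == 0:
        raise UndefinedIndexError(
            f"item {freqs.item_id!r}: SI undefined (A+O+M+I = 0)"
        )
    return (freqs.count(_A) + freqs.count(_O)) / denom


def importance_index(freqs: ItemFrequencies) -> float:
    """DSI = -(O+M)/(A+O+M+I); R and Q counts are ignored."""
    denom = _classifiable(freqs)
    if denom == 0:
        raise UndefinedIndexError(
            f"item {freqs.item_id!r}: DSI undefined (A+O+M+I = 0)"
        )
    return -(freqs.count(_O) + freqs.count(_M)) / denom


def round_display(x: float, decimals: int = 2) -> float:
    """Round half away from zero, matching how survey tables are printed."""
    q = Decimal(1).scaleb(-decimals)
    magnitude = Decimal(repr(abs(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(magnitude if x >= 0 else -magnitude)


def item_results(freq_rows: Sequence[ItemFrequencies]) -> list[ItemResult]:
    """Compute category + indices for every item, in input order."""
    return [
        ItemResult(
            item_id=f.item_id,
            frequencies=f,
            classification=modal_category(f),
            si=satisfaction_index(f),
            dsi=importance_index(f),
        )
        for f in freq_rows
    ]


def compute_origin(
    results: Iterable[ItemResult], *, from_rounded: bool = False
) -> MatrixOrigin:
    """Per-axis means of (|DSI|, SI) over items.

    ``from_rounded`` averages the 2-dp display values instead of the
    full-precision ones — useful when replicating a published table that
    only prints rounded indices.  Full precision is the default.
    """
    results = list(results)
    if not results:
        raise NoDataError("cannot compute an origin from zero items")
    if from_rounded:
        xs = [abs(round_display(r.dsi)) for r in results]
        ys = [round_display(r.si) for r in results]
    else:
        xs = [abs(r.dsi) for r in results]
        ys = [r.si for r in results]
    return MatrixOrigin(x0=sum(xs) / len(xs), y0=sum(ys) / len(ys))


def assign_quadrant(si: float, dsi: float, origin: MatrixOrigin) -> Quadrant:
    """Place an item, comparing |DSI| against x0 and SI against y0."""
    x = abs(dsi)
    if si >= origin.y0:
        return Quadrant.I if x >= origin.x0 else Quadrant.II
    return Quadrant.IV if x >= origin.x0 else Quadrant.III


def build_matrix(
    results: Sequence[ItemResult], origin: MatrixOrigin | None = None
) -> tuple[list[ItemResult], MatrixOrigin, dict[Quadrant, list[str]]]:
    """Assign every item to its quadrant and list memberships.

    Returns (results with quadrants filled in, the origin used, and a
    quadrant -> sorted item-id listing).  The origin defaults to the
    full-precision per-axis means of the supplied results.
    """
    if origin is None:
        origin = compute_origin(results)
    placed = [
        replace(r, quadrant=assign_quadrant(r.si, r.dsi, origin)) for r in results
    ]
    membership: dict[Quadrant, list[str]] = {q: [] for q in Quadrant}
    for r in placed:
        membership[r.quadrant].append(r.item_id)  # type: ignore[index]
    for q in membership:
        membership[q].sort(key=_natural_key)
    return placed, origin, membership


def _natural_key(item_id: str):
    return (0, int(item_id)) if item_id.isdigit() else (1, item_id)
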