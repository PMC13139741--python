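"""Per-item tabulation of pair classifications and modal attribute assignment.

An item's *frequency row* counts how many respondents fell into each of
the six categories; the item's final Kano attribute is the modal (most
frequent) category.  Ties are broken by the fixed precedence
M > O > A > I > R > Q — the convention that categories with the larger
dissatisfaction impact dominate — and are always flagged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import (
    CATEGORY_ORDER,
    KanoCategory,
    NoDataError,
    ResponsePair,
    ValidationError,
    classify_pair,
)


@dataclass(frozen=True)
class ItemFrequencies:
    """Counts of the six Kano categories for one item.

    The conservation invariant sum(counts) == n_total is enforced at
    construction; n_total is the number of respondents with a complete,
    valid pair for this item.  Reverse and questionable answers are kept
    in the row (they are excluded only from the SI/DSI denominator,
    never from the tabulation).
    """

    item_id: str
    counts: Mapping[KanoCategory, int]
    label: str = ""

    def __post_init__(self) -> None:
        full = {c: int(self.counts.get(c, 0)) for c in CATEGORY_ORDER}
        if any(v < 0 for v in full.values()):
            raise ValidationError(f"negative category count for item {self.item_id!r}")
        object.__setattr__(self, "counts", full)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def count(self, category: KanoCategory) -> int:
        return self.counts[category]

    @classmethod
    def from_counts(
        cls,
        item_id: str,
        *,
        M: int = 0,
        O: int = 0,
        A: int = 0,
        I: int = 0,
        R: int = 0,
        Q: int = 0,
        label: str = "",
    ) -> "ItemFrequencies":
        """Convenience constructor keyed by the one-letter tags."""
        return cls(
            item_id=item_id,
            counts={KanoCategory.from_tag(t): v for t, v in
                    [("M", M), ("O", O), ("A", A), ("I", I), ("R", R), ("Q", Q)]},
            label=label,
        )


@dataclass(frozen=True)
class ItemClassification:
    """Modal Kano attribute for one item, with tie diagnostics."""

    item_id: str
    category: KanoCategory
    is_tie: bool = False
    tied_categories: frozenset[KanoCategory] = field(default_factory=frozenset)


def tabulate_item(
    responses: Iterable[ResponsePair], item_id: str, label: str = ""
) -> ItemFrequencies:
    """Count pair-level classifications into one frequency row."""
    counts = {c: 0 for c in CATEGORY_ORDER}
    n = 0
    for pair in responses:
        counts[classify_pair(pair)] += 1
        n += 1
    if n == 0:
        raise NoDataError(f"no responses for item {item_id!r}")
    return ItemFrequencies(item_id=item_id, counts=counts, label=label)


def modal_category(freqs: ItemFrequencies) -> ItemClassification:
    """Assign the item's attribute as the most frequent category.

    Ties go to the earlier category in CATEGORY_ORDER (M > O > A > I >
    R > Q); ``is_tie`` records that the maximum was shared.
    """
    if freqs.n_total == 0:
        raise NoDataError(f"all counts zero for item {freqs.item_id!r}")
    best = max(freqs.counts.values())
    tied = frozenset(c for c in CATEGORY_ORDER if freqs.counts[c] == best)
    winner = next(c for c in CATEGORY_ORDER if c in tied)
    return ItemClassification(
        item_id=freqs.item_id,
        category=winner,
        is_tie=len(tied) > 1,
        tied_categories=tied,
    )


def classify_all(
    dataset: Sequence[ItemFrequencies] | Mapping[str, Sequence[ResponsePair]],
) -> list[ItemClassification]:
    """Classify every item, preserving the dataset's item order.

    Accepts either pre-aggregated frequency rows or a mapping from item
    id to that item's response pairs; both paths yield identical results
    (tabulate-then-classify commutes with per-respondent classification).
    """
    if isinstance(dataset, Mapping):
        freq_rows = [tabulate_item(pairs, item_id) for item_id, pairs in dataset.items()]
    else:
        freq_rows = list(dataset)
    if not freq_rows:
        raise NoDataError("dataset contains no items")
    return [modal_category(f) for f in freq_rows]


def attribute_tally(
    classifications: Iterable[ItemClassification],
) -> dict[KanoCategory, int]:
    """How many items landed in each category (zero-count categories omitted)."""
    tally: dict[KanoCategory, int] = {}
    for cls_ in classifications:
        tally[cls_.category] = tally.get(cls_.category, 0) + 1
    return tally
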