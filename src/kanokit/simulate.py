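"""Synthetic paired-Likert respondents with controlled Kano structure.

Each item is described by a probability distribution over the 25
(functional, dysfunctional) answer cells.  Respondents draw every item
independently from that item's distribution (no latent respondent
trait), so the expected frequency row — and hence the expected modal
category, SI and DSI — is known exactly in advance.  Completion times
are lognormal and logic-error flags Bernoulli, so the screening stage
can be exercised end to end.  Everything is reproducible from the seed.

Two shorthands build common profiles:

* ``ItemProfile.from_category("A", purity=0.8)`` puts 80% of the mass
  uniformly on the attractive cells of the evaluation table and spreads
  the rest uniformly over all other cells (maximum-entropy default).
* ``profile_from_frequencies(row)`` converts an observed frequency row
  into the profile whose implied category distribution matches it,
  letting a published aggregate table seed realistic simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aggregate import ItemFrequencies
from .core import (
    CATEGORY_ORDER,
    KanoCategory,
    LikertLevel,
    NoDataError,
    ResponsePair,
    ValidationError,
    classify_pair,
    evaluation_table,
)
from .screening import RespondentRecord

Cell = tuple[int, int]  # (functional code, dysfunctional code), each 1..5

#: All 25 cells in row-major order; the sampling order of every profile.
ALL_CELLS: tuple[Cell, ...] = tuple((f, d) for f in range(1, 6) for d in range(1, 6))

_CELLS_BY_CATEGORY: dict[KanoCategory, tuple[Cell, ...]] = {}
for (_f, _d), _cat in evaluation_table().items():
    _CELLS_BY_CATEGORY.setdefault(_cat, ())
    _CELLS_BY_CATEGORY[_cat] += ((int(_f), int(_d)),)


def cells_for_category(category: KanoCategory) -> tuple[Cell, ...]:
    """The evaluation-table cells that classify to ``category``."""
    return _CELLS_BY_CATEGORY[category]


@dataclass(frozen=True)
class ItemProfile:
    """Distribution over the 25 answer cells for one item."""

    item_id: str
    cell_weights: Mapping[Cell, float]
    label: str = ""

    def __post_init__(self) -> None:
        weights = {c: float(self.cell_weights.get(c, 0.0)) for c in ALL_CELLS}
        if any(w < 0 for w in weights.values()):
            raise ValidationError(f"item {self.item_id!r}: negative cell weight")
        total = sum(weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"item {self.item_id!r}: cell weights sum to {total}, not 1"
            )
        object.__setattr__(self, "cell_weights", weights)

    @classmethod
    def from_category(
        cls, item_id: str, target: KanoCategory | str, purity: float = 1.0,
        label: str = "",
    ) -> "ItemProfile":
        """Mass ``purity`` uniform on the target's cells, rest uniform elsewhere."""
        if not 0.0 <= purity <= 1.0:
            raise ValidationError(f"purity must be in [0,1], got {purity}")
        cat = KanoCategory.from_tag(target) if isinstance(target, str) else target
        inside = cells_for_category(cat)
        outside = tuple(c for c in ALL_CELLS if c not in inside)
        weights = {c: purity / len(inside) for c in inside}
        if outside:
            for c in outside:
                weights[c] = (1.0 - purity) / len(outside)
        return cls(item_id=item_id, cell_weights=weights, label=label)

    def implied_category_distribution(self) -> dict[KanoCategory, float]:
        """Exact category probabilities this profile induces."""
        dist = {c: 0.0 for c in CATEGORY_ORDER}
        for (f, d), w in self.cell_weights.items():
            dist[classify_pair(ResponsePair(LikertLevel(f), LikertLevel(d)))] += w
        return dist

    def implied_indices(self) -> tuple[float, float]:
        """(SI, DSI) implied by the profile's category distribution."""
        p = self.implied_category_distribution()
        a, o = p[KanoCategory.ATTRACTIVE], p[KanoCategory.ONE_DIMENSIONAL]
        m, i = p[KanoCategory.MUST_BE], p[KanoCategory.INDIFFERENT]
        denom = a + o + m + i
        if denom == 0:
            raise NoDataError(f"item {self.item_id!r}: no classifiable mass")
        return (a + o) / denom, -(o + m) / denom


def profile_from_frequencies(freqs: ItemFrequencies) -> ItemProfile:
    """Profile whose implied category distribution matches observed counts.

    Each category's observed share is spread uniformly over that
    category's cells (the maximum-entropy choice given only the
    category-level counts).
    """
    if freqs.n_total == 0:
        raise NoDataError(f"item {freqs.item_id!r}: empty frequency row")
    weights: dict[Cell, float] = {}
    for cat in CATEGORY_ORDER:
        share = freqs.count(cat) / freqs.n_total
        if share == 0:
            continue
        cells = cells_for_category(cat)
        for c in cells:
            weights[c] = weights.get(c, 0.0) + share / len(cells)
    return ItemProfile(item_id=freqs.item_id, cell_weights=weights, label=freqs.label)


@dataclass(frozen=True)
class CompletionTimeModel:
    """Lognormal completion times, parameterised by log-scale mu/sigma.

    Defaults give a median of about 7 minutes with roughly 4-5% of
    respondents under the 180 s screening threshold.
    """

    mu: float = math.log(420.0)
    sigma: float = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic survey."""

    profiles: Sequence[ItemProfile]
    n_respondents: int
    seed: int
    completion_time: CompletionTimeModel = CompletionTimeModel()
    logic_error_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValidationError("n_respondents must be >= 1")
        if not 0.0 <= self.logic_error_rate <= 1.0:
            raise ValidationError("logic_error_rate must be in [0,1]")
        if not self.profiles:
            raise ValidationError("spec needs at least one item profile")


def generate(spec: SyntheticSpec) -> list[RespondentRecord]:
    """Draw the full respondent-level dataset described by ``spec``.

    Each respondent draws each item i.i.d. from that item's cell
    distribution; completion times and logic flags come from their own
    models.  Identical spec + seed reproduces the dataset exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_respondents
    # one multinomial draw stream per item, row-major over respondents
    item_draws: dict[str, np.ndarray] = {}
    for profile in spec.profiles:
        p = np.array([profile.cell_weights[c] for c in ALL_CELLS])
        item_draws[profile.item_id] = rng.choice(len(ALL_CELLS), size=n, p=p)
    times = rng.lognormal(spec.completion_time.mu, spec.completion_time.sigma, size=n)
    logic = rng.random(size=n) < spec.logic_error_rate
    width = len(str(n))
    records = []
    for i in range(n):
        responses = {
            profile.item_id: ResponsePair(
                LikertLevel(ALL_CELLS[item_draws[profile.item_id][i]][0]),
                LikertLevel(ALL_CELLS[item_draws[profile.item_id][i]][1]),
            )
            for profile in spec.profiles
        }
        records.append(
            RespondentRecord(
                respondent_id=f"r{i + 1:0{width}d}",
                responses=responses,
                completion_seconds=float(times[i]),
                logic_error=bool(logic[i]),
            )
        )
    return records
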