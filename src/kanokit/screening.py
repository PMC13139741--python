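"""Respondent screening, response-rate accounting and sample-size planning.

Screening drops respondents in two disjoint passes: records flagged with
an obvious logical error first, then — among the remainder — records
completed faster than a minimum plausible time (default 180 s).  What
counts as a "logical error" is survey-specific, so the caller supplies
the boolean flag (or computes it with their own detector); this module
only does the accounting.

Sample-size planning follows Kendall's rule of thumb: a questionnaire
with k independent variables needs 5-10 times k respondents, inflated
for anticipated non-response (default 20%, i.e. a 1.2 multiplier).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import NoDataError, ResponsePair
from .indices import round_display


@dataclass
class RespondentRecord:
    """One respondent: metadata plus their per-item answer pairs."""

    respondent_id: str
    responses: Mapping[str, ResponsePair] = field(default_factory=dict)
    completion_seconds: float = math.inf
    logic_error: bool = False

    def __post_init__(self) -> None:
        if self.completion_seconds < 0:
            raise ValueError(
                f"respondent {self.respondent_id!r}: negative completion time"
            )


@dataclass(frozen=True)
class ScreeningReport:
    """Exclusion tallies and the resulting response rate."""

    n_received: int
    n_logic_excluded: int
    n_time_excluded: int

    @property
    def n_valid(self) -> int:
        return self.n_received - self.n_logic_excluded - self.n_time_excluded

    @property
    def response_rate_pct(self) -> float:
        """Valid / received as a percentage, rounded to 2 dp for display."""
        if self.n_received == 0:
            return 0.0
        return round_display(100.0 * self.n_valid / self.n_received)

    def to_dict(self) -> dict:
        return {
            "n_received": self.n_received,
            "n_logic_excluded": self.n_logic_excluded,
            "n_time_excluded": self.n_time_excluded,
            "n_valid": self.n_valid,
            "response_rate_pct": self.response_rate_pct,
        }


def screen(
    records: Sequence[RespondentRecord], min_seconds: float = 180.0
) -> tuple[list[RespondentRecord], ScreeningReport]:
    """Apply the two-pass exclusion and return kept records + report.

    Logic-flagged records are removed first; the time filter then applies
    only to the remainder, so the two printed exclusion counts are
    disjoint and sum with n_valid to n_received.  Input order of the
    kept records is preserved.
    """
    if min_seconds < 0:
        raise ValueError("min_seconds must be non-negative")
    if not records:
        raise NoDataError("no questionnaires received")
    after_logic = [r for r in records if not r.logic_error]
    kept = [r for r in after_logic if r.completion_seconds >= min_seconds]
    report = ScreeningReport(
        n_received=len(records),
        n_logic_excluded=len(records) - len(after_logic),
        n_time_excluded=len(after_logic) - len(kept),
    )
    return kept, report


@dataclass(frozen=True)
class SampleSizePlan:
    """Kendall-rule sample-size range for a k-variable questionnaire."""

    k_variables: int
    nonresponse_inflation: float = 1.2
    multiplier_low: int = 5
    multiplier_high: int = 10

    @property
    def n_min(self) -> int:
        return math.ceil(self.k_variables * self.multiplier_low * self.nonresponse_inflation)

    @property
    def n_max(self) -> int:
        return math.ceil(self.k_variables * self.multiplier_high * self.nonresponse_inflation)


def kendall_sample_size(k: int, inflation: float = 1.2) -> SampleSizePlan:
    """Plan the 5x-10x sample-size range, ceiling fractional products."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    if inflation < 1:
        raise ValueError("inflation must be >= 1")
    return SampleSizePlan(k_variables=k, nonresponse_inflation=inflation)
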