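"""End-to-end analysis: screen -> tabulate -> classify -> indices -> matrix.

``run_pipeline`` accepts either respondent-level records (which are
screened and tabulated) or pre-aggregated frequency rows (which skip
screening) and produces a single :class:`AnalysisReport`.  Per-stage
record counts are logged to stderr, mirroring the exclusion accounting
a survey report prints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .aggregate import ItemFrequencies, attribute_tally, tabulate_item
from .core import KanoCategory, NoDataError
from .indices import (
    ItemResult,
    MatrixOrigin,
    Quadrant,
    build_matrix,
    compute_origin,
    item_results,
)
from .io import Codebook, report_to_dict
from .screening import RespondentRecord, ScreeningReport, screen

logger = logging.getLogger("kanokit")


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one pipeline run produced."""

    items: Sequence[ItemResult]
    origin: MatrixOrigin
    quadrant_membership: Mapping[Quadrant, Sequence[str]]
    attribute_tally: Mapping[KanoCategory, int]
    screening: ScreeningReport | None = None

    def to_dict(self) -> dict:
        return report_to_dict(
            list(self.items),
            self.origin,
            {q: list(ids) for q, ids in self.quadrant_membership.items()},
            self.screening,
        )


def tabulate_records(
    records: Sequence[RespondentRecord], codebook: Codebook
) -> list[ItemFrequencies]:
    """One frequency row per codebook item from screened records."""
    rows = []
    for it in codebook.items:
        pairs = [
            r.responses[it.item_id] for r in records if it.item_id in r.responses
        ]
        if not pairs:
            raise NoDataError(f"item {it.item_id!r} has zero valid respondents")
        rows.append(tabulate_item(pairs, it.item_id, label=it.label))
    return rows


def run_pipeline(
    data: Sequence[RespondentRecord] | Sequence[ItemFrequencies],
    codebook: Codebook | None = None,
    *,
    min_seconds: float = 180.0,
    origin: MatrixOrigin | None = None,
) -> AnalysisReport:
    """Run the full analysis and return a deterministic report.

    Respondent-level input requires a codebook and passes through
    screening first; frequency-row input is analysed as-is.
    """
    screening_report: ScreeningReport | None = None
    if data and isinstance(data[0], RespondentRecord):
        if codebook is None:
            raise ValueError("respondent-level input requires a codebook")
        records = list(data)  # type: ignore[arg-type]
        logger.info("screening: %d questionnaires received", len(records))
        kept, screening_report = screen(records, min_seconds=min_seconds)
        logger.info(
            "screening: %d logic-excluded, %d time-excluded, %d valid (%.2f%%)",
            screening_report.n_logic_excluded,
            screening_report.n_time_excluded,
            screening_report.n_valid,
            screening_report.response_rate_pct,
        )
        freq_rows = tabulate_records(kept, codebook)
    else:
        freq_rows = list(data)  # type: ignore[arg-type]
    if not freq_rows:
        raise NoDataError("no items to analyse")
    logger.info("classifying %d items", len(freq_rows))
    results = item_results(freq_rows)
    if origin is None:
        origin = compute_origin(results)
    placed, origin, membership = build_matrix(results, origin)
    logger.info(
        "matrix origin (|DSI|, SI) = (%.4f, %.4f); quadrant sizes %s",
        origin.x0,
        origin.y0,
        {q.name: len(ids) for q, ids in membership.items()},
    )
    return AnalysisReport(
        items=placed,
        origin=origin,
        quadrant_membership=membership,
        attribute_tally=attribute_tally(r.classification for r in placed),
        screening=screening_report,
    )
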