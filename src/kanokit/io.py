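"""Readers and writers for survey tables, codebooks and result reports.

Two input dialects are accepted:

* **respondent-level wide CSV** — one row per respondent, two Likert
  columns (functional, dysfunctional) per item, plus optional
  ``completion_seconds`` and ``logic_error`` metadata columns; which
  columns belong to which item is declared in a codebook (YAML/JSON);
* **aggregated frequency table** (CSV/TSV) — one row per item with
  columns ``item, label, M, O, A, I, R, Q``, for studies that publish
  only the per-item category counts.

All files are UTF-8; the Unicode minus sign often found in published
tables is normalised to ASCII ``-`` on read.  Writers round only at the
display layer: the JSON report carries full-precision indices, so
re-reading it reproduces identical downstream results.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .aggregate import ItemFrequencies
from .core import LikertLevel, ResponsePair, ValidationError
from .indices import ItemResult, MatrixOrigin, Quadrant, round_display
from .screening import RespondentRecord, ScreeningReport

_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-", "—": "-"})


@dataclass(frozen=True)
class CodebookItem:
    item_id: str
    label: str
    functional_column: str
    dysfunctional_column: str


@dataclass(frozen=True)
class Codebook:
    """Declares the survey's items and which data columns hold them."""

    items: Sequence[CodebookItem]
    display_decimals: int = 2
    respondent_id_column: str = "respondent_id"
    completion_seconds_column: str = "completion_seconds"
    logic_error_column: str = "logic_error"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError("codebook item ids are not unique")

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        items = [
            CodebookItem(
                item_id=str(it["item_id"]),
                label=str(it.get("label", it["item_id"])),
                functional_column=str(it["functional_column"]),
                dysfunctional_column=str(it["dysfunctional_column"]),
            )
            for it in d["items"]
        ]
        kwargs = {
            k: d[k]
            for k in (
                "display_decimals",
                "respondent_id_column",
                "completion_seconds_column",
                "logic_error_column",
            )
            if k in d
        }
        return cls(items=tuple(items), **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "Codebook":
        """Load a YAML or JSON codebook."""
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def default(cls, item_ids: Iterable[str]) -> "Codebook":
        """Codebook with the F<i>/D<i> column convention."""
        return cls(
            items=tuple(
                CodebookItem(str(i), str(i), f"F{i}", f"D{i}") for i in item_ids
            )
        )


def read_survey(path: str | Path, codebook: Codebook) -> list[RespondentRecord]:
    """Read a respondent-level wide CSV into validated records.

    Cells that cannot be parsed as a Likert code 1-5 abort the read with
    an error listing every offending (row, column) coordinate.  A pair
    with either side missing is dropped for that item only.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    for it in codebook.items:
        for col in (it.functional_column, it.dysfunctional_column):
            if col not in frame.columns:
                raise ValidationError(
                    f"codebook references missing column {col!r} in {path}"
                )
    bad_cells: list[str] = []
    records: list[RespondentRecord] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        row_d = dict(zip(frame.columns, row))
        responses: dict[str, ResponsePair] = {}
        for it in codebook.items:
            f_raw = row_d.get(it.functional_column)
            d_raw = row_d.get(it.dysfunctional_column)
            if pd.isna(f_raw) or pd.isna(d_raw):
                continue  # incomplete pair: drop for this item only
            try:
                responses[it.item_id] = ResponsePair(
                    LikertLevel.from_code(str(f_raw).strip()),
                    LikertLevel.from_code(str(d_raw).strip()),
                )
            except ValidationError:
                bad_cells.append(
                    f"row {row_no}, columns {it.functional_column}/"
                    f"{it.dysfunctional_column}: ({f_raw!r}, {d_raw!r})"
                )
        rid = str(row_d.get(codebook.respondent_id_column, f"row{row_no}"))
        secs_raw = row_d.get(codebook.completion_seconds_column)
        secs = float("inf") if secs_raw is None or pd.isna(secs_raw) else float(secs_raw)
        logic_raw = row_d.get(codebook.logic_error_column)
        logic = str(logic_raw).strip().lower() in {"1", "true", "yes"} if (
            logic_raw is not None and not pd.isna(logic_raw)
        ) else False
        records.append(
            RespondentRecord(
                respondent_id=rid,
                responses=responses,
                completion_seconds=secs,
                logic_error=logic,
            )
        )
    if bad_cells:
        raise ValidationError(
            "invalid Likert codes:\n  " + "\n  ".join(bad_cells)
        )
    return records


def records_to_frame(
    records: Sequence[RespondentRecord], codebook: Codebook
) -> pd.DataFrame:
    """Serialise records back to the wide CSV layout the reader accepts."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            codebook.respondent_id_column: r.respondent_id,
            codebook.completion_seconds_column: round(r.completion_seconds, 1),
            codebook.logic_error_column: int(r.logic_error),
        }
        for it in codebook.items:
            pair = r.responses.get(it.item_id)
            if pair is not None:
                row[it.functional_column] = int(pair.functional)
                row[it.dysfunctional_column] = int(pair.dysfunctional)
        rows.append(row)
    columns = [
        codebook.respondent_id_column,
        codebook.completion_seconds_column,
        codebook.logic_error_column,
    ]
    for it in codebook.items:
        columns += [it.functional_column, it.dysfunctional_column]
    return pd.DataFrame(rows, columns=columns)


_FREQ_TAGS = ("M", "O", "A", "I", "R", "Q")


def read_frequency_table(path: str | Path) -> list[ItemFrequencies]:
    """Read an aggregated per-item frequency table (CSV or TSV).

    Needs columns ``item`` and the six tags M O A I R Q; ``label`` is
    optional.  The delimiter is sniffed from the first line.
    """
    text = Path(path).read_text(encoding="utf-8").translate(_MINUS_VARIANTS)
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    if reader.fieldnames is None:
        raise ValidationError(f"{path}: empty frequency table")
    missing = [c for c in ("item", *_FREQ_TAGS) if c not in reader.fieldnames]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    rows = []
    for rec in reader:
        try:
            counts = {tag: int(rec[tag]) for tag in _FREQ_TAGS}
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer count in row {rec}") from exc
        rows.append(
            ItemFrequencies.from_counts(
                str(rec["item"]).strip(),
                label=str(rec.get("label", "") or "").strip(),
                **counts,
            )
        )
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    return rows


def write_results_table(
    results: Sequence[ItemResult], path: str | Path, decimals: int = 2
) -> None:
    """Write the per-item results as a TSV with display-rounded indices."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["item", "label", *_FREQ_TAGS, "attribute", "DSI", "SI", "quadrant"]
        )
        for r in results:
            writer.writerow(
                [
                    r.item_id,
                    r.label,
                    *[r.frequencies.counts[c] for c in r.frequencies.counts],
                    r.category.tag,
                    f"{round_display(r.dsi, decimals):.{decimals}f}",
                    f"{round_display(r.si, decimals):.{decimals}f}",
                    r.quadrant.name if r.quadrant else "",
                ]
            )


def report_to_dict(
    results: Sequence[ItemResult],
    origin: MatrixOrigin,
    membership: dict[Quadrant, list[str]],
    screening: ScreeningReport | None = None,
) -> dict:
    """Full-precision JSON-ready report of an analysis run."""
    tally: dict[str, int] = {}
    for r in results:
        tally[r.category.tag] = tally.get(r.category.tag, 0) + 1
    out: dict = {
        "items": [
            {
                "item_id": r.item_id,
                "label": r.label,
                "counts": {c.tag: v for c, v in r.frequencies.counts.items()},
                "n_total": r.frequencies.n_total,
                "attribute": r.category.tag,
                "is_tie": r.classification.is_tie,
                "si": r.si,
                "dsi": r.dsi,
                "quadrant": r.quadrant.name if r.quadrant else None,
            }
            for r in results
        ],
        "origin": {"x0": origin.x0, "y0": origin.y0},
        "attribute_tally": tally,
        "quadrant_membership": {q.name: ids for q, ids in membership.items()},
    }
    if screening is not None:
        out["screening"] = screening.to_dict()
    return out


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
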