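"""Google-Trends-dialect CSV input/output and censored-value imputation.

Google Trends exports monthly "interest over time" tables (integer RSV
0-100, with the censoring token ``<1`` for nonzero interest below 1%)
and "compared breakdown by region" tables (per-country shares of two
compared topics summing to 100, blank cells for countries masked for low
search volume).  This module parses and writes those dialects and applies
the study's imputation rule: ``<1`` -> 0.5 and ``0`` -> 0.1, so that
ratios against the benchmark topic are always finite.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: sentinel for the "<1" censoring token in raw series
CENSORED = "<1"

#: imputed numeric value for "<1" tokens
CENSORED_VALUE = 0.5
#: imputed numeric value for exact-zero RSV
ZERO_VALUE = 0.1

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")
_WEEKLY_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


class GTParseError(ValueError):
    """Malformed Google-Trends-dialect input."""


@dataclass
class TopicSeries:
    """One topic's monthly RSV series for one region scope.

    ``values`` holds raw tokens (ints and the ``CENSORED`` sentinel) when
    ``imputed`` is False, and positive floats after imputation.
    """

    topic_id: str
    region: str
    months: pd.PeriodIndex
    values: np.ndarray
    imputed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float if self.imputed else object)
        if len(self.values) != len(self.months):
            raise ValueError("values and months differ in length")
        if len(self.months) > 1:
            steps = np.diff(self.months.asi8)
            if not np.all(steps == 1):
                raise ValueError("months must be consecutive calendar months")

    def __len__(self) -> int:
        return len(self.months)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months.astype(str), self.topic_id: self.values})


@dataclass
class RegionShareTable:
    """Per-country shares of one topic vs the reference, summing to 100.

    ``shares`` maps country -> (share_topic, share_reference) with raw
    tokens, or ``None`` for a country masked by Google Trends.
    """

    topic_id: str
    reference_id: str
    shares: dict[str, tuple[object, object] | None]
    imputed: bool = False

    @property
    def countries(self) -> list[str]:
        return list(self.shares)

    def masked_countries(self) -> list[str]:
        return [c for c, v in self.shares.items() if v is None]


def _parse_token(cell: str, row_no: int):
    cell = cell.strip()
    if cell in ("<1", "<1%"):
        return CENSORED
    if cell.endswith("%"):
        cell = cell[:-1]
    try:
        value = int(cell)
    except ValueError:
        raise GTParseError(f"row {row_no}: unparseable RSV value {cell!r}") from None
    if not 0 <= value <= 100:
        raise GTParseError(f"row {row_no}: RSV {value} outside [0, 100]")
    return value


def _split_header_query(q: str) -> tuple[str, str]:
    """GT headers look like 'itch: (Worldwide)'; fall back to the bare name."""
    m = re.match(r"^(.*?):\s*\((.*)\)$", q.strip())
    if m:
        return m.group(1).strip(), m.group(2).strip()
    return q.strip(), "world"


def parse_interest_over_time(csv_text: str) -> list[TopicSeries]:
    """Parse a GT "interest over time" CSV into raw TopicSeries, one per column.

    Accepts up to two preamble lines (a "Category: ..." banner and a blank
    line) before the ``Month,<query>[,<query>]`` header.  Weekly exports
    (``YYYY-MM-DD`` dates) are rejected: the pipeline is monthly-only.
    """
    lines = csv_text.splitlines()
    start = 0
    while start < len(lines) and (
        not lines[start].strip() or lines[start].startswith("Category:")
    ):
        start += 1
        if start > 2:
            raise GTParseError("too many preamble lines before header")
    if start >= len(lines):
        raise GTParseError("no header row found")
    header = next(csv_rows([lines[start]]))
    if not header or header[0].strip().lower() != "month":
        raise GTParseError(f"expected 'Month' header, got {header[:1]!r}")
    queries = [_split_header_query(q) for q in header[1:]]
    if not queries:
        raise GTParseError("header has no query columns")

    months: list[pd.Period] = []
    columns: list[list[object]] = [[] for _ in queries]
    for row_no, row in enumerate(csv_rows(lines[start + 1:]), start=start + 2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        stamp = row[0].strip()
        if _WEEKLY_RE.match(stamp):
            raise GTParseError(
                f"row {row_no}: weekly export detected ({stamp!r}); only monthly data is supported"
            )
        m = _MONTH_RE.match(stamp)
        if not m or not 1 <= int(m.group(2)) <= 12:
            raise GTParseError(f"row {row_no}: malformed month {stamp!r}")
        if len(row) != len(queries) + 1:
            raise GTParseError(f"row {row_no}: expected {len(queries) + 1} cells, got {len(row)}")
        months.append(pd.Period(stamp, "M"))
        for col, cell in zip(columns, row[1:]):
            col.append(_parse_token(cell, row_no))

    if not months:
        raise GTParseError("no data rows")
    idx = pd.PeriodIndex(months, freq="M")
    if len(idx) > 1 and not np.all(np.diff(idx.asi8) == 1):
        raise GTParseError("months are not contiguous")
    return [
        TopicSeries(topic_id=name, region=region, months=idx, values=np.array(col, dtype=object))
        for (name, region), col in zip(queries, columns)
    ]


def csv_rows(lines: Sequence[str]):
    import csv

    yield from csv.reader(lines)


def parse_interest_by_region(csv_text: str) -> RegionShareTable:
    """Parse a GT "compared breakdown by region" CSV (two compared topics)."""
    lines = [ln for ln in csv_text.splitlines() if ln.strip() or True]
    start = 0
    while start < len(lines) and (
        not lines[start].strip() or lines[start].startswith("Category:")
    ):
        start += 1
    header = next(csv_rows([lines[start]]))
    if len(header) != 3 or header[0].strip().lower() not in ("country", "region"):
        raise GTParseError("expected header 'Country,<topic>,<reference>'")
    topic_id = _split_header_query(header[1])[0]
    reference_id = _split_header_query(header[2])[0]

    shares: dict[str, tuple[object, object] | None] = {}
    for row_no, row in enumerate(csv_rows(lines[start + 1:]), start=start + 2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        country = row[0].strip()
        cells = [c.strip() for c in row[1:]]
        if len(cells) != 2:
            raise GTParseError(f"row {row_no}: expected 2 share cells for {country}")
        if all(c in ("", "0") for c in cells):
            shares[country] = None
            continue
        pair = tuple(_parse_token(c, row_no) if c else 0 for c in cells)
        if pair == (0, 0):
            shares[country] = None
            continue
        numeric = [CENSORED_VALUE if v == CENSORED else float(v) for v in pair]
        if not 99.0 <= sum(numeric) <= 101.0:
            raise GTParseError(
                f"row {row_no}: shares for {country} sum to {sum(numeric):g}, not 100"
            )
        shares[country] = pair
    return RegionShareTable(topic_id=topic_id, reference_id=reference_id, shares=shares)


def impute_censored(s: TopicSeries) -> TopicSeries:
    """Apply the study's imputation: ``<1`` -> 0.5, ``0`` -> 0.1.

    Integer RSV values pass through unchanged.  Imputing twice is a
    contract error (the rule is defined on raw tokens only).
    """
    if s.imputed:
        raise ValueError(f"series {s.topic_id!r} is already imputed")
    out = np.empty(len(s), dtype=float)
    for i, v in enumerate(s.values):
        if v == CENSORED:
            out[i] = CENSORED_VALUE
        elif v == 0:
            out[i] = ZERO_VALUE
        else:
            out[i] = float(v)
    return replace(s, values=out, imputed=True)


def impute_shares(t: RegionShareTable) -> RegionShareTable:
    """Imputation rule applied to region shares; masked rows stay masked."""
    if t.imputed:
        raise ValueError("share table is already imputed")

    def imp(v):
        if v == CENSORED:
            return CENSORED_VALUE
        if v == 0:
            return ZERO_VALUE
        return float(v)

    shares = {
        c: None if pair is None else (imp(pair[0]), imp(pair[1]))
        for c, pair in t.shares.items()
    }
    return replace(t, shares=shares, imputed=True)


def format_series_csv(series_list: list[TopicSeries], category_line: bool = True) -> str:
    """Render TopicSeries back to the GT interest-over-time dialect."""
    if not series_list:
        raise ValueError("no series to write")
    months = series_list[0].months
    for s in series_list[1:]:
        if not s.months.equals(months):
            raise ValueError("series do not share months")
    buf = io.StringIO()
    if category_line:
        buf.write("Category: All categories\n\n")
    buf.write("Month," + ",".join(s.topic_id for s in series_list) + "\n")
    for i, month in enumerate(months):
        cells = []
        for s in series_list:
            v = s.values[i]
            if v == CENSORED:
                cells.append("<1")
            elif s.imputed:
                cells.append(f"{float(v):g}")
            else:
                cells.append(str(int(v)))
        buf.write(str(month) + "," + ",".join(cells) + "\n")
    return buf.getvalue()


def format_region_csv(t: RegionShareTable, category_line: bool = True) -> str:
    buf = io.StringIO()
    if category_line:
        buf.write("Category: All categories\n\n")
    buf.write(f"Country,{t.topic_id},{t.reference_id}\n")
    for country, pair in t.shares.items():
        if pair is None:
            buf.write(f"{country},,\n")
        else:
            cells = ["<1" if v == CENSORED else f"{v:g}" for v in pair]
            buf.write(f"{country},{cells[0]},{cells[1]}\n")
    return buf.getvalue()


def write_table(rows, path, fmt: str = "csv", report_mode: bool = False) -> None:
    """Write a result table as CSV or JSON with a deterministic column order.

    Report mode renders floats with 2 decimals (the precision the study's
    tables use); machine mode keeps full precision.
    """
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    if df.empty:
        raise ValueError("refusing to write an empty table")
    if fmt == "csv":
        float_format = "%.2f" if report_mode else None
        df.to_csv(path, index=False, float_format=float_format)
    elif fmt == "json":
        if report_mode:
            df = df.round(2)
        df.to_json(path, orient="records", indent=1)
    else:
        raise ValueError(f"unknown table format: {fmt!r}")
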