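"""Data model and tabular I/O for individual case safety reports (ICSRs).

One CSV row per report; list-valued cells (drugs, reactions, outcomes) are
serialized with a ``|`` secondary delimiter, escaped with a backslash.
Missing markers: empty string for strings, empty cell for age; a sex of
``U`` is normalized to missing on read.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "ATC5_PATTERN",
    "OUTCOME_TERMS",
    "AtcError",
    "DrugMention",
    "IcsrReport",
    "IcsrValidationError",
    "atc_ancestor",
    "atc_level",
    "filter_by_date_window",
    "read_reports",
    "write_reports",
]

ATC5_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: Seriousness/outcome flags carried per report.  An empty set means the
#: outcome classification is missing, which is distinct from "no outcome".
OUTCOME_TERMS = frozenset(
    {
        "death",
        "hospitalization",
        "clinically_important",
        "life_threatening",
        "disability",
        "congenital_anomaly",
    }
)

_LEVEL_BY_LEN = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
_LEN_BY_LEVEL = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

CSV_COLUMNS = [
    "report_id",
    "report_date",
    "reporter_hcp",
    "sex",
    "age_years",
    "outcomes",
    "drug_atc5_list",
    "drug_inn_list",
    "reaction_pt_list",
]


class IcsrValidationError(ValueError):
    """A report or file failed validation."""


class AtcError(ValueError):
    """An ATC code is malformed or a hierarchy request is impossible."""


def atc_level(code: str) -> int:
    """Return the ATC hierarchy level (1-5) implied by the code length."""
    try:
        return _LEVEL_BY_LEN[len(code)]
    except KeyError:
        raise AtcError(f"invalid ATC code length for {code!r}") from None


def atc_ancestor(code: str, level: int) -> str:
    """Truncate an ATC code to its ancestor at ``level`` (prefix rule).

    ``atc_ancestor("B01AE07", 2) == "B01"``.  Requesting a level above the
    code's own level raises :class:`AtcError`.
    """
    if level not in _LEN_BY_LEVEL:
        raise AtcError(f"ATC level must be 1-5, got {level}")
    own = atc_level(code)
    if level > own:
        raise AtcError(f"cannot take level-{level} ancestor of level-{own} code {code!r}")
    return code[: _LEN_BY_LEVEL[level]]


@dataclass(frozen=True)
class DrugMention:
    """One suspected drug on a report: ATC level-5 code (optional) + INN."""

    atc5: Optional[str]
    inn: str

    def __post_init__(self) -> None:
        if self.atc5 is not None and not ATC5_PATTERN.match(self.atc5):
            raise IcsrValidationError(f"malformed ATC5 code: {self.atc5!r}")
        if not self.inn:
            raise IcsrValidationError("drug mention requires a substance name")


@dataclass(frozen=True)
class IcsrReport:
    """One spontaneous report.

    ``outcomes`` is a set of :data:`OUTCOME_TERMS`; empty means the outcome
    classification is missing.  Drugs are deduplicated on (atc5, inn) so a
    product listed twice (e.g. two dose forms) counts once.
    """

    report_id: str
    report_date: dt.date
    reporter_hcp: Optional[bool]
    sex: Optional[str]
    age_years: Optional[float]
    outcomes: frozenset
    drugs: tuple
    reactions: tuple

    def __post_init__(self) -> None:
        if not self.report_id:
            raise IcsrValidationError("report_id must be non-empty")
        if self.sex not in (None, "F", "M"):
            raise IcsrValidationError(f"sex must be F, M or missing, got {self.sex!r}")
        if self.age_years is not None and not (0 <= self.age_years <= 120):
            raise IcsrValidationError(
                f"age_years out of [0, 120] in report {self.report_id}: {self.age_years}"
            )
        bad = set(self.outcomes) - OUTCOME_TERMS
        if bad:
            raise IcsrValidationError(f"unknown outcome terms {sorted(bad)}")
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))
        if not self.drugs:
            raise IcsrValidationError(f"report {self.report_id} has an empty drug list")
        if not self.reactions:
            raise IcsrValidationError(f"report {self.report_id} has an empty reaction list")
        # dedup drugs on (atc5, inn), preserving first-seen order
        seen, dedup = set(), []
        for d in self.drugs:
            key = (d.atc5, d.inn)
            if key not in seen:
                seen.add(key)
                dedup.append(d)
        object.__setattr__(self, "drugs", tuple(dedup))
        object.__setattr__(self, "reactions", tuple(self.reactions))


# ---------------------------------------------------------------------------
# list-in-cell serialization: "|" delimiter, backslash escaping
# ---------------------------------------------------------------------------


def _escape_item(item: str) -> str:
    return item.replace("\\", "\\\\").replace("|", "\\|")


def _join_list(items: Iterable[str]) -> str:
    return "|".join(_escape_item(i) for i in items)


def _split_list(cell: str) -> list:
    """Split an escaped ``|``-delimited cell; '' yields ['']."""
    items, buf, it = [], [], iter(cell)
    for ch in it:
        if ch == "\\":
            nxt = next(it, "")
            buf.append(nxt)
        elif ch == "|":
            items.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    items.append("".join(buf))
    return items


def _format_bool(v: Optional[bool]) -> str:
    return "" if v is None else ("true" if v else "false")


def _parse_bool(cell: str, row: int) -> Optional[bool]:
    cell = cell.strip().lower()
    if cell == "":
        return None
    if cell in ("true", "1", "yes"):
        return True
    if cell in ("false", "0", "no"):
        return False
    raise IcsrValidationError(f"row {row}: cannot parse boolean {cell!r}")


def _report_to_row(r: IcsrReport) -> list:
    return [
        r.report_id,
        r.report_date.isoformat(),
        _format_bool(r.reporter_hcp),
        r.sex or "",
        "" if r.age_years is None else repr(float(r.age_years)),
        _join_list(sorted(r.outcomes)),
        _join_list("" if d.atc5 is None else d.atc5 for d in r.drugs),
        _join_list(d.inn for d in r.drugs),
        _join_list(r.reactions),
    ]


def _row_to_report(row: dict, rownum: int) -> IcsrReport:
    rid = row["report_id"].strip()
    if not rid:
        raise IcsrValidationError(f"row {rownum}: empty report_id")
    try:
        date = dt.date.fromisoformat(row["report_date"].strip())
    except ValueError as exc:
        raise IcsrValidationError(f"row {rownum}: bad report_date: {exc}") from None
    sex = row["sex"].strip().upper()
    sex_val = None if sex in ("", "U") else sex
    age_cell = row["age_years"].strip()
    age = None if age_cell == "" else float(age_cell)
    out_cell = row["outcomes"]
    outcomes = frozenset(t for t in _split_list(out_cell) if t) if out_cell else frozenset()

    inns = _split_list(row["drug_inn_list"])
    if inns == [""]:
        raise IcsrValidationError(f"row {rownum} (report {rid}): empty drug list")
    atc_cells = _split_list(row["drug_atc5_list"])
    if len(atc_cells) != len(inns):
        raise IcsrValidationError(
            f"row {rownum} (report {rid}): drug_atc5_list has {len(atc_cells)} items "
            f"but drug_inn_list has {len(inns)}"
        )
    try:
        drugs = tuple(
            DrugMention(atc5=a if a else None, inn=i) for a, i in zip(atc_cells, inns)
        )
    except IcsrValidationError as exc:
        raise IcsrValidationError(f"row {rownum} (report {rid}): {exc}") from None

    rx_cell = row["reaction_pt_list"]
    reactions = tuple(t for t in _split_list(rx_cell) if t) if rx_cell else ()
    if not reactions:
        raise IcsrValidationError(f"row {rownum} (report {rid}): empty reaction list")

    try:
        return IcsrReport(
            report_id=rid,
            report_date=date,
            reporter_hcp=_parse_bool(row["reporter_hcp"], rownum),
            sex=sex_val,
            age_years=age,
            outcomes=outcomes,
            drugs=drugs,
            reactions=reactions,
        )
    except IcsrValidationError as exc:
        raise IcsrValidationError(f"row {rownum}: {exc}") from None


def read_reports(path, dialect: Optional[dict] = None) -> list:
    """Read an ICSR CSV into validated :class:`IcsrReport` values.

    Row order is preserved.  Duplicate report ids, malformed ATC codes and
    empty drug/reaction lists raise :class:`IcsrValidationError` naming the
    offending row.
    """
    path = Path(path)
    opts = dict(dialect or {})
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **opts)
        if reader.fieldnames is None:
            raise IcsrValidationError(f"{path}: empty file, header required")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise IcsrValidationError(f"{path}: missing required columns {missing}")
        reports, seen = [], set()
        for rownum, row in enumerate(reader, start=2):
            rep = _row_to_report(row, rownum)
            if rep.report_id in seen:
                raise IcsrValidationError(
                    f"row {rownum}: duplicate report_id {rep.report_id!r}"
                )
            seen.add(rep.report_id)
            reports.append(rep)
    return reports


def write_reports(reports: Sequence[IcsrReport], path) -> None:
    """Write reports to CSV so that ``read_reports`` round-trips exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in reports:
            writer.writerow(_report_to_row(r))


def filter_by_date_window(
    reports: Iterable[IcsrReport],
    date_from: Optional[dt.date] = None,
    date_to: Optional[dt.date] = None,
) -> list:
    """Keep reports whose date falls in the inclusive [date_from, date_to] window."""
    out = []
    for r in reports:
        if date_from is not None and r.report_date < date_from:
            continue
        if date_to is not None and r.report_date > date_to:
            continue
        out.append(r)
    return out
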