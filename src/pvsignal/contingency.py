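"""Drug-mention expansion, combination rules and 2x2 table construction.

The unit of counting is the drug MENTION (one distinct drug on one report),
not the report.  Fixed clinical combinations (e.g. sulfamethoxazole +
trimethoprim) are collapsed to a single labelled entity before counting.
Mentions with a missing ATC5 code cannot be placed in the hierarchy: they
stay in the mention totals but are excluded from entity cells and sibling
comparators, and surface in an "unclassified" bucket for auditing.
"""

from __future__ import annotations

import csv
import fnmatch
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from pvsignal.icsr import IcsrReport, atc_ancestor, atc_level

__all__ = [
    "CombinationRule",
    "ContingencyTable",
    "DegenerateComparatorError",
    "MentionTable",
    "build_table",
    "entity_counts",
    "expand_mentions",
    "filter_min_cases",
    "load_combination_rules",
]

logger = logging.getLogger(__name__)

COMPARATORS = ("siblings_within_parent", "all_other")


class DegenerateComparatorError(ValueError):
    """The comparator set is empty (entity equals its whole class)."""


@dataclass(frozen=True)
class CombinationRule:
    """Collapse member drugs to one entity labelled ``combined_label``.

    Members are matched by exact ATC5 code or by a case-insensitive glob on
    the substance name (e.g. ``amoxicillin and *inhibitor*``).
    """

    combined_label: str
    members: frozenset

    def matches(self, atc5: Optional[str], inn: str) -> bool:
        for m in self.members:
            if atc5 is not None and atc5 == m:
                return True
            if fnmatch.fnmatch(inn.casefold(), m.casefold()):
                return True
        return False


def load_combination_rules(path) -> list:
    """Read rules from a CSV with columns combined_label, member_match."""
    rules: dict = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "combined_label",
            "member_match",
        } <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns combined_label, member_match")
        for row in reader:
            rules.setdefault(row["combined_label"].strip(), set()).add(
                row["member_match"].strip()
            )
    out = [CombinationRule(label, frozenset(members)) for label, members in rules.items()]
    _check_disjoint(out)
    return out


def _check_disjoint(rules: Sequence[CombinationRule]) -> None:
    seen: dict = {}
    for r in rules:
        for m in r.members:
            if m in seen and seen[m] != r.combined_label:
                raise ValueError(
                    f"member {m!r} appears in rules {seen[m]!r} and {r.combined_label!r}"
                )
            seen[m] = r.combined_label


@dataclass
class MentionTable:
    """One row per distinct (report, entity) pair after combination collapse.

    Columns: report_id, is_case, entity5 (ATC5 code, combined label, or NA
    for missing ATC5), atc2 (NA when not derivable), inn.
    """

    frame: pd.DataFrame

    @property
    def n_case_mentions(self) -> int:
        return int(self.frame["is_case"].sum())

    @property
    def n_noncase_mentions(self) -> int:
        return int((~self.frame["is_case"]).sum())

    @property
    def n_unclassified(self) -> int:
        return int(self.frame["entity5"].isna().sum())


def _mention_rows(report: IcsrReport, is_case: bool, rules: Sequence[CombinationRule]):
    collapsed: dict = {}
    plain = []
    for d in report.drugs:
        rule = next((r for r in rules if r.matches(d.atc5, d.inn)), None)
        if rule is None:
            plain.append(d)
        else:
            collapsed.setdefault(rule.combined_label, []).append(d)
    rows = []
    for d in plain:
        atc2 = atc_ancestor(d.atc5, 2) if d.atc5 is not None else None
        rows.append((report.report_id, is_case, d.atc5, atc2, d.inn))
    for label, members in collapsed.items():
        parents = {atc_ancestor(d.atc5, 2) for d in members if d.atc5 is not None}
        atc2 = parents.pop() if len(parents) == 1 else None
        rows.append((report.report_id, is_case, label, atc2, label))
    return rows


def expand_mentions(
    cases: Iterable[IcsrReport],
    noncases: Iterable[IcsrReport],
    rules: Sequence[CombinationRule] = (),
) -> MentionTable:
    """Expand classified reports into a mention table.

    Every distinct (report, drug) pair yields one row; drugs matching a
    combination rule collapse to the rule's label (one mention even if
    several members appear on the same report).
    """
    rows = []
    for r in cases:
        rows.extend(_mention_rows(r, True, rules))
    for r in noncases:
        rows.extend(_mention_rows(r, False, rules))
    frame = pd.DataFrame(
        rows, columns=["report_id", "is_case", "entity5", "atc2", "inn"]
    ).astype({"report_id": "string", "entity5": "string", "atc2": "string", "inn": "string"})
    table = MentionTable(frame)
    if table.n_unclassified:
        logger.info(
            "mention table: %d case / %d non-case mentions, %d with missing ATC5",
            table.n_case_mentions,
            table.n_noncase_mentions,
            table.n_unclassified,
        )
    return table


def _entity_column(level: int) -> str:
    if level == 5:
        return "entity5"
    if level == 2:
        return "atc2"
    raise ValueError(f"level must be 2 or 5, got {level}")


def entity_counts(mentions: MentionTable, level: int) -> pd.DataFrame:
    """Per-entity case/non-case mention counts at ATC level 2 or 5.

    Mentions whose entity is NA at the requested level are dropped here
    (they remain in the table totals).
    """
    col = _entity_column(level)
    f = mentions.frame.dropna(subset=[col])
    g = f.groupby(col, observed=True)["is_case"]
    out = pd.DataFrame(
        {
            "entity": g.sum().index,
            "case_mentions": g.sum().to_numpy().astype(int),
            "noncase_mentions": (g.count() - g.sum()).to_numpy().astype(int),
        }
    )
    return out.sort_values("entity", ignore_index=True)


def filter_min_cases(
    mentions: MentionTable, entity_level: int, min_cases: int
) -> pd.DataFrame:
    """Entities with at least ``min_cases`` case mentions at the given level."""
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    counts = entity_counts(mentions, entity_level)
    return counts[counts["case_mentions"] >= min_cases].reset_index(drop=True)


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table with provenance.

    a/b: case/non-case mentions of the entity; c/d: the comparator set.
    Cells are floats so the Haldane-corrected table uses the same type.
    """

    entity: str
    level: int
    comparator: str
    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    def cells(self):
        return (self.a, self.b, self.c, self.d)


def _parent_of(mentions: MentionTable, entity: str, level: int) -> Optional[str]:
    if level == 2:
        return entity[:1]
    try:
        if atc_level(entity) == 5:
            return atc_ancestor(entity, 2)
    except Exception:
        pass  # combined label: derive parent from its own rows
    parents = mentions.frame.loc[mentions.frame["entity5"] == entity, "atc2"].dropna().unique()
    return parents[0] if len(parents) == 1 else None


def build_table(
    mentions: MentionTable,
    entity: str,
    level: int,
    comparator: str = "siblings_within_parent",
) -> ContingencyTable:
    """Build the 2x2 table for one entity.

    ``siblings_within_parent``: the comparator is the other members of the
    entity's parent class (other drugs of the same ATC2 at level 5; other
    ATC2 classes under the same ATC1 at level 2).  ``all_other``: the
    comparator is every other mention in the database, so a+c and b+d equal
    the database-wide mention totals.
    """
    if comparator not in COMPARATORS:
        raise ValueError(f"comparator must be one of {COMPARATORS}, got {comparator!r}")
    col = _entity_column(level)
    f = mentions.frame
    mask = f[col] == entity
    a = int((mask & f["is_case"]).sum())
    b = int((mask & ~f["is_case"]).sum())

    if comparator == "all_other":
        c = mentions.n_case_mentions - a
        d = mentions.n_noncase_mentions - b
    else:
        parent = _parent_of(mentions, entity, level)
        if parent is None:
            raise DegenerateComparatorError(
                f"entity {entity!r} has no unique parent class; "
                "use comparator='all_other'"
            )
        if level == 5:
            in_parent = f["atc2"] == parent
        else:
            in_parent = f["atc2"].str.startswith(parent).fillna(False)
        c = int((in_parent & f["is_case"]).sum()) - a
        d = int((in_parent & ~f["is_case"]).sum()) - b
    if c == 0 and d == 0:
        raise DegenerateComparatorError(
            f"comparator set for {entity!r} is empty (entity equals its class); "
            "use comparator='all_other'"
        )
    return ContingencyTable(
        entity=entity, level=level, comparator=comparator, a=a, b=b, c=c, d=d
    )


def table_from_counts(
    entity: str, level: int, comparator: str, a: float, b: float, c: float, d: float
) -> ContingencyTable:
    """Convenience constructor for a table given pre-computed cells."""
    return ContingencyTable(
        entity=entity, level=level, comparator=comparator, a=a, b=b, c=c, d=d
    )
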