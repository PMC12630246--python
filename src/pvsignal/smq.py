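"""Case classification by exact Preferred-Term matching against an SMQ list.

Matching is exact on normalized strings (trimmed, case-folded) — never
fuzzy or substring — because an SMQ is a curated term set and approximate
matching would silently change case counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Tuple

from pvsignal.icsr import IcsrReport

__all__ = ["SmqDefinition", "load_smq", "classify_report", "classify_all"]


def _normalize(term: str) -> str:
    return term.strip().casefold()


@dataclass(frozen=True)
class SmqDefinition:
    """A named set of MedDRA Preferred Terms defining case status."""

    name: str
    scope: str  # "narrow" or "broad"; carried, not interpreted
    terms: frozenset

    def __post_init__(self) -> None:
        if self.scope not in ("narrow", "broad"):
            raise ValueError(f"scope must be 'narrow' or 'broad', got {self.scope!r}")
        if not self.terms:
            raise ValueError("SMQ term set must be non-empty")
        object.__setattr__(self, "terms", frozenset(_normalize(t) for t in self.terms))

    def matches(self, pt: str) -> bool:
        return _normalize(pt) in self.terms


def load_smq(path, name: str, scope: str = "narrow") -> SmqDefinition:
    """Load a plain-text term list (one PT per line, ``#`` comments allowed)."""
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        terms.add(_normalize(line))
    if not terms:
        raise ValueError(f"{path}: no terms after normalization")
    return SmqDefinition(name=name, scope=scope, terms=frozenset(terms))


def classify_report(report: IcsrReport, smq: SmqDefinition) -> bool:
    """True iff at least one reaction PT belongs to the SMQ (a "case")."""
    return any(smq.matches(pt) for pt in report.reactions)


def classify_all(
    reports: Iterable[IcsrReport], smq: SmqDefinition
) -> Tuple[list, list]:
    """Partition reports into (cases, noncases); order preserved in each."""
    cases, noncases = [], []
    for r in reports:
        (cases if classify_report(r, smq) else noncases).append(r)
    return cases, noncases
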