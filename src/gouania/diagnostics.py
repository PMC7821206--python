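"""Range-nonoverlap diagnostics between species.

A morphometric character is diagnostic between two species when their value
ranges (holotype united with the paratype range) do not overlap, so any
specimen can be assigned unambiguously on that character alone. Ranges that
merely touch at an endpoint are treated as overlapping: a specimen at the
shared value would be ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .morphometrics import Interval, SpeciesRangeTable

__all__ = ["intervals_disjoint", "diagnostic_characters", "diagnose", "DiagnosticReport"]


def intervals_disjoint(a: Interval, b: Interval) -> bool:
    """True iff the closed intervals share no point (touching counts as overlap)."""
    return a.hi < b.lo or b.hi < a.lo


@dataclass
class DiagnosticReport:
    focal: str
    comparators: tuple[str, ...]
    mode: str
    characters: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.characters)


def diagnose(
    focal: str,
    comparators: Iterable[str],
    table: SpeciesRangeTable,
    mode: Literal["all", "any"] = "all",
) -> DiagnosticReport:
    """Enumerate characters separating ``focal`` from ``comparators`` by range.

    mode="all": the focal range must be disjoint from every comparator's range
    (the convention behind "nonoverlapping in range with all ..." statements).
    mode="any": disjoint from at least one comparator.

    Characters missing for any involved species are skipped and listed in the
    report rather than counted, which keeps the diagnosis conservative.
    Character order follows the table row order.
    """
    comparators = tuple(comparators)
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    if not comparators:
        raise ValueError("at least one comparator species is required")
    if focal in comparators:
        raise ValueError(f"focal species {focal!r} cannot be its own comparator")
    for sp in (focal, *comparators):
        if sp not in table.species:
            raise KeyError(f"unknown species {sp!r}")

    report = DiagnosticReport(focal=focal, comparators=comparators, mode=mode)
    for character in table.characters(focal):
        if not all(table.has(sp, character) for sp in comparators):
            report.skipped.append(character)
            continue
        focal_range = table.combined(focal, character)
        disjoint = [
            intervals_disjoint(focal_range, table.combined(sp, character))
            for sp in comparators
        ]
        if (mode == "all" and all(disjoint)) or (mode == "any" and any(disjoint)):
            report.characters.append(character)
    return report


def diagnostic_characters(
    focal: str,
    comparators: Iterable[str],
    table: SpeciesRangeTable,
    mode: Literal["all", "any"] = "all",
) -> list[str]:
    """Character names separating ``focal`` from ``comparators``; see :func:`diagnose`."""
    return diagnose(focal, comparators, table, mode).characters
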