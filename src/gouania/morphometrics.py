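"""Morphometric measurement system for *Gouania* clingfishes.

All body measurements are taken in mm and expressed relative to standard
length (SL): either as percentages of SL (the convention of the species
range table) or as "times in SL" ratios (the convention of running-text
descriptions, e.g. "disc length 5.0-6.3 in SL"). This module houses the
controlled character vocabulary, the closed-interval type used by all
range logic, and the conversions between the three scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "CHARACTERS",
    "SPECIES",
    "SL_ROW",
    "Interval",
    "SpecimenMeasurements",
    "SpeciesRangeTable",
    "round1",
    "percent_sl",
    "combined_range",
    "pct_to_sl_ratio",
]

#: The five species covered by the range table, in the table's column order.
SPECIES = (
    "G. adriatica",
    "G. orientalis",
    "G. hofrichteri",
    "G. pigra",
    "G. willdenowi",
)

#: Row label of the standard-length row; it is the normaliser, not a character.
SL_ROW = "Standard length (SL) in mm"

#: Controlled vocabulary of the 25 morphometric characters (%SL rows of the
#: range table), in table row order (alphabetical).
CHARACTERS = (
    "Body depth at anus",
    "Body depth at pectoral fins",
    "Body width at anus",
    "Body width at pectoral fins",
    "Caudal base depth",
    "Caudal fin length",
    "Disc length",
    "Disc width",
    "Distance between the posterior margin of sucking disc and anus",
    "Head depth at anterior sucking disc edge",
    "Head depth at orbit",
    "Head length",
    "Head width at head invagination",
    "Head width at orbit",
    "Head width at sucking disc anterior edge",
    "Horizontal eye diameter",
    "Interorbital distance",
    "Pectoral fin length",
    "Postanus length",
    "Postorbital distance",
    "Preanus length",
    "Predisc length",
    "Preorbital distance",
    "Prepectoral-fin length",
    "Vertical eye diameter",
)


def round1(x: float) -> float:
    """Round half-up to one decimal, the display precision of the range table.

    Python's built-in ``round`` rounds half to even; printed morphometric
    tables conventionally round half up, so 20.05 -> 20.1.
    """
    return math.floor(x * 10.0 + 0.5) / 10.0


@dataclass(frozen=True, order=True)
class Interval:
    """Closed numeric interval [lo, hi]; hosts every printed range."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError(f"interval bounds must be finite, got {self}")
        if self.lo > self.hi:
            raise ValueError(f"interval lower bound exceeds upper: {self}")

    def __contains__(self, value: float) -> bool:
        return self.lo <= value <= self.hi

    def contains_interval(self, other: "Interval") -> bool:
        return self.lo <= other.lo and other.hi <= self.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


def percent_sl(measure_mm: float, sl_mm: float, *, round_1dp: bool = False) -> float:
    """Express a measurement as a percentage of standard length.

    Parameters
    ----------
    measure_mm : measurement in mm, must be >= 0.
    sl_mm : standard length in mm, must be > 0.
    round_1dp : if True, round half-up to one decimal (table precision).
    """
    if not sl_mm > 0:
        raise ValueError(f"standard length must be positive, got {sl_mm}")
    if measure_mm < 0:
        raise ValueError(f"measurement must be non-negative, got {measure_mm}")
    pct = 100.0 * measure_mm / sl_mm
    return round1(pct) if round_1dp else pct


def combined_range(holotype_value: float, others: Interval) -> Interval:
    """Combine a holotype/neotype value with the paratype range.

    The table reports the name-bearing specimen separately from the range of
    the remaining type series; all between-species comparisons use the union
    [min(holotype, lo), max(holotype, hi)].
    """
    if not math.isfinite(holotype_value):
        raise ValueError("holotype value must be finite")
    return Interval(min(holotype_value, others.lo), max(holotype_value, others.hi))


def pct_to_sl_ratio(range_pct: Interval) -> Interval:
    """Convert a %SL range to the "times in SL" convention.

    A measure of p %SL goes p/100 times into SL, i.e. the ratio is 100/p;
    the order of the bounds reverses. Bounds are reported rounded half-up to
    one decimal, matching the running-text precision.
    """
    if range_pct.lo <= 0:
        raise ValueError(f"percentage range must be strictly positive, got {range_pct}")
    return Interval(round1(100.0 / range_pct.hi), round1(100.0 / range_pct.lo))


@dataclass
class SpecimenMeasurements:
    """Raw measurements (mm) for one specimen.

    ``measurements`` maps character names (a subset of :data:`CHARACTERS`)
    to lengths in mm; missing characters are simply absent from the map.
    """

    specimen_id: str
    sl_mm: float
    species_label: str | None = None
    measurements: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sl_mm > 0:
            raise ValueError(
                f"{self.specimen_id}: standard length must be positive, got {self.sl_mm}"
            )
        for name, value in self.measurements.items():
            if name not in CHARACTERS:
                raise ValueError(
                    f"{self.specimen_id}: unknown character {name!r}"
                )
            if value < 0:
                raise ValueError(
                    f"{self.specimen_id}: negative measurement for {name!r}"
                )

    def percent_sl(self, character: str, *, round_1dp: bool = False) -> float:
        """The named measurement as %SL."""
        return percent_sl(self.measurements[character], self.sl_mm, round_1dp=round_1dp)

    def as_percent_sl(self, *, round_1dp: bool = False) -> dict[str, float]:
        return {
            name: percent_sl(value, self.sl_mm, round_1dp=round_1dp)
            for name, value in self.measurements.items()
        }


class SpeciesRangeTable:
    """Per-species, per-character %SL values: holotype plus paratype range.

    The machine form of the published morphometric table. Standard length is
    carried alongside (in mm) but excluded from the character rows.
    """

    def __init__(
        self,
        rows: Mapping[str, Mapping[str, tuple[float, float, float]]],
        sl_rows: Mapping[str, tuple[float, float, float]] | None = None,
    ) -> None:
        self._rows: dict[str, dict[str, tuple[float, float, float]]] = {
            sp: dict(chars) for sp, chars in rows.items()
        }
        self._sl: dict[str, tuple[float, float, float]] = dict(sl_rows or {})
        for sp, chars in self._rows.items():
            for name, (holo, lo, hi) in chars.items():
                if name not in CHARACTERS:
                    raise ValueError(f"{sp}: unknown character {name!r}")
                if lo > hi:
                    raise ValueError(f"{sp}/{name}: range lower bound exceeds upper")
                if not all(0 < v < 100 for v in (holo, lo, hi)):
                    raise ValueError(f"{sp}/{name}: %SL values must lie in (0, 100)")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._rows)

    def characters(self, species: str | None = None) -> tuple[str, ...]:
        """Character rows present (table row order)."""
        if species is None:
            return tuple(
                c for c in CHARACTERS if all(c in chars for chars in self._rows.values())
            )
        return tuple(c for c in CHARACTERS if c in self._species_rows(species))

    def _species_rows(self, species: str) -> dict[str, tuple[float, float, float]]:
        try:
            return self._rows[species]
        except KeyError:
            raise KeyError(
                f"unknown species {species!r}; expected one of {sorted(self._rows)}"
            ) from None

    def holotype(self, species: str, character: str) -> float:
        return self._species_rows(species)[character][0]

    def others_range(self, species: str, character: str) -> Interval:
        _, lo, hi = self._species_rows(species)[character]
        return Interval(lo, hi)

    def combined(self, species: str, character: str) -> Interval:
        """Holotype value united with the paratype range."""
        holo, lo, hi = self._species_rows(species)[character]
        return combined_range(holo, Interval(lo, hi))

    def has(self, species: str, character: str) -> bool:
        return character in self._species_rows(species)

    def sl_span(self, species: str) -> Interval:
        """Standard-length span (mm) of the whole type series."""
        holo, lo, hi = self._sl[species]
        return combined_range(holo, Interval(lo, hi))

    def genus_extremes(self, character: str, species: Iterable[str] | None = None) -> Interval:
        """Union of combined ranges across species: the genus-wide envelope."""
        names = tuple(species) if species is not None else self.species
        ranges = [self.combined(sp, character) for sp in names if self.has(sp, character)]
        if not ranges:
            raise KeyError(f"no species carries character {character!r}")
        return Interval(min(r.lo for r in ranges), max(r.hi for r in ranges))
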