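"""Partially specified calendar dates.

Trial registries record dates as "November 2016" or "January 1, 2006": the
day of month is frequently absent. All audit logic (completion windows,
publication-before-completion screens) therefore compares dates at *month*
precision; the day is carried through parsing but never consulted.
"""
from __future__ import annotations

import calendar
import re
from dataclasses import dataclass

__all__ = ["PartialDate", "DateParseError", "parse_partial_date", "months_between"]


class DateParseError(ValueError):
    """A date string could not be interpreted as a registry date."""


_MONTH_NUMBERS: dict[str, int] = {}
for _i in range(1, 13):
    _MONTH_NUMBERS[calendar.month_name[_i].lower()] = _i
    _MONTH_NUMBERS[calendar.month_abbr[_i].lower()] = _i

_MONTH_DAY_YEAR = re.compile(r"^([A-Za-z]+)\s+(\d{1,2}),\s*(\d{4})$")
_MONTH_YEAR = re.compile(r"^([A-Za-z]+)\s+(\d{4})$")
_ISO_FULL = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_ISO_MONTH = re.compile(r"^(\d{4})-(\d{1,2})$")


@dataclass(frozen=True)
class PartialDate:
    """A year/month/optional-day calendar value.

    Ordering operators compare at month precision only: ``a < b`` iff
    ``(a.year, a.month) < (b.year, b.month)``. Note that equality (``==``)
    still compares all three fields, so two dates in the same month with
    different days satisfy ``a <= b and b <= a`` without ``a == b``; use
    :attr:`month_key` when a total order over months is needed.
    """

    year: int
    month: int
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1900 <= self.year <= 2100:
            raise ValueError(f"year out of range: {self.year}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and not 1 <= self.day <= 31:
            raise ValueError(f"day out of range: {self.day}")

    @property
    def month_key(self) -> tuple[int, int]:
        """The (year, month) pair used for every comparison in the audit."""
        return (self.year, self.month)

    def __lt__(self, other: "PartialDate") -> bool:
        return self.month_key < other.month_key

    def __le__(self, other: "PartialDate") -> bool:
        return self.month_key <= other.month_key

    def __gt__(self, other: "PartialDate") -> bool:
        return self.month_key > other.month_key

    def __ge__(self, other: "PartialDate") -> bool:
        return self.month_key >= other.month_key

    def isoformat(self) -> str:
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def registry_format(self) -> str:
        """Render in the registry's textual dialect ("Month [DD, ]YYYY")."""
        name = calendar.month_name[self.month]
        if self.day is None:
            return f"{name} {self.year}"
        return f"{name} {self.day}, {self.year}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def parse_partial_date(text: str) -> PartialDate:
    """Parse a registry-style or ISO date string into a :class:`PartialDate`.

    Accepted forms: ``"November 2016"``, ``"January 1, 2006"``, ``"2016-11"``,
    ``"2016-11-01"``. Anything else raises :class:`DateParseError`.
    """
    if text is None or not text.strip():
        raise DateParseError("empty date string")
    s = text.strip()

    m = _MONTH_DAY_YEAR.match(s)
    if m:
        month = _MONTH_NUMBERS.get(m.group(1).lower())
        if month is None:
            raise DateParseError(f"unknown month name in {text!r}")
        return PartialDate(int(m.group(3)), month, int(m.group(2)))
    m = _MONTH_YEAR.match(s)
    if m:
        month = _MONTH_NUMBERS.get(m.group(1).lower())
        if month is None:
            raise DateParseError(f"unknown month name in {text!r}")
        return PartialDate(int(m.group(2)), month)
    m = _ISO_FULL.match(s)
    if m:
        return PartialDate(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    m = _ISO_MONTH.match(s)
    if m:
        return PartialDate(int(m.group(1)), int(m.group(2)))
    raise DateParseError(f"unparseable date: {text!r}")


def months_between(start: PartialDate, end: PartialDate) -> int:
    """Exact calendar-month difference ``(end - start)``, day ignored.

    Positive when ``end`` is after ``start``; e.g. June 2010 → October 2016
    is 76 months.
    """
    return (end.year - start.year) * 12 + (end.month - start.month)
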