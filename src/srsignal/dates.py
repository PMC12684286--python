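"""Partial calendar dates as they appear in spontaneous reporting systems.

SRS databases record dates with varying completeness: a therapy-start field
may hold a full day (``20210403``), a year-month (``202104``), a bare year,
or nothing.  Time-to-onset analysis requires complete dates on both ends;
everything else must be representable but excluded, never imputed.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional

__all__ = ["PartialDate", "parse_partial_date"]

_MISSING_TOKENS = {"", "-", "--", "不明", "unknown", "unk", "na", "nan", "none"}


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date in which month and/or day may be unknown.

    Invariants: a day is never present without a month; month/day ranges are
    validated at construction.  ``is_complete`` additionally requires the
    three components to form a valid calendar date.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("PartialDate cannot have a day without a month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and not 1 <= self.day <= 31:
            raise ValueError(f"day out of range: {self.day}")

    @property
    def is_complete(self) -> bool:
        """True iff year, month and day are present and form a real date."""
        if self.month is None or self.day is None:
            return False
        try:
            _dt.date(self.year, self.month, self.day)
        except ValueError:
            return False
        return True

    def to_date(self) -> _dt.date:
        if not self.is_complete:
            raise ValueError(f"not a complete date: {self}")
        return _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def compact(self) -> str:
        """Render in the compact SRS form: YYYYMMDD, YYYYMM or YYYY."""
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}{self.month:02d}{self.day:02d}"


_SEPARATED = re.compile(r"^(\d{4})[/\-.](\d{1,2})(?:[/\-.](\d{1,2}))?$")


def parse_partial_date(text: Optional[str]) -> Optional[PartialDate]:
    """Parse a raw SRS date field into a :class:`PartialDate`.

    Accepts compact digit forms (``YYYYMMDD``, ``YYYYMM``, ``YYYY``) and
    separator forms (``YYYY/MM/DD``, ``YYYY-MM``).  Missing-value tokens and
    unparseable text return ``None``.  A day component that does not form a
    valid calendar date (e.g. February 30th) is treated as ambiguous and the
    date degrades to year-month, so it can never qualify as complete.
    """
    if text is None:
        return None
    s = str(text).strip()
    if s.isdigit():  # the overwhelmingly common case in SRS extracts
        if len(s) == 8:
            return _build(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return _build(int(s[:4]), int(s[4:6]), None)
        if len(s) == 4:
            return PartialDate(int(s))
        return None
    if s.lower() in _MISSING_TOKENS:
        return None
    m = _SEPARATED.match(s)
    if m:
        y, mo = int(m.group(1)), int(m.group(2))
        d = int(m.group(3)) if m.group(3) else None
        return _build(y, mo, d)
    return None


def _build(year: int, month: int, day: Optional[int]) -> Optional[PartialDate]:
    if not 1 <= month <= 12:
        return PartialDate(year)
    if day is None:
        return PartialDate(year, month)
    try:
        _dt.date(year, month, day)
    except ValueError:
        return PartialDate(year, month)  # ambiguous day -> incomplete
    return PartialDate(year, month, day)
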