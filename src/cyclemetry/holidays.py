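"""Holiday calendar construction and the holiday-smooth transform.

Claims data show sharp diagnosis-rate dips in weeks containing major
holidays: practices close and patients defer visits.  These dips are
reporting artifacts, not disease dynamics, so they are offset before model
fitting by replacing each holiday-week value with the average of the
surrounding non-holiday weeks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml


def easter_date(year: int) -> dt.date:
    """Easter Sunday by the anonymous Gregorian computus.

    Valid for Gregorian years (>= 1583).
    """
    if year < 1583:
        raise ValueError("Gregorian computus is undefined before 1583")
    a = year % 19
    b, c = divmod(year, 100)
    d, e = divmod(b, 4)
    f = (b + 8) // 25
    g = (b - f + 1) // 3
    h = (19 * a + b - d - g + 15) % 30
    i, k = divmod(c, 4)
    l = (32 + 2 * e + 2 * i - h - k) % 7
    m = (a + 11 * h + 22 * l) // 451
    month, day = divmod(h + l - 7 * m + 114, 31)
    return dt.date(year, month, day + 1)


def good_friday(year: int) -> dt.date:
    return easter_date(year) - dt.timedelta(days=2)


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    """n-th (1-based) given weekday of a month; n=-1 means last."""
    if n > 0:
        first = dt.date(year, month, 1)
        offset = (weekday - first.weekday()) % 7
        return first + dt.timedelta(days=offset + 7 * (n - 1))
    if month == 12:
        last = dt.date(year, 12, 31)
    else:
        last = dt.date(year, month + 1, 1) - dt.timedelta(days=1)
    offset = (last.weekday() - weekday) % 7
    return last - dt.timedelta(days=offset)


def us_federal_holidays(year: int) -> list[dt.date]:
    """The 10 US federal holidays observed 2003-2014, as calendar dates.

    Observed-on-Friday/Monday substitutions are irrelevant at weekly
    resolution and are not applied.
    """
    return [
        dt.date(year, 1, 1),                    # New Year's Day
        _nth_weekday(year, 1, 0, 3),            # Martin Luther King Jr. Day
        _nth_weekday(year, 2, 0, 3),            # Washington's Birthday
        _nth_weekday(year, 5, 0, -1),           # Memorial Day
        dt.date(year, 7, 4),                    # Independence Day
        _nth_weekday(year, 9, 0, 1),            # Labor Day
        _nth_weekday(year, 10, 0, 2),           # Columbus Day
        dt.date(year, 11, 11),                  # Veterans Day
        _nth_weekday(year, 11, 3, 4),           # Thanksgiving
        dt.date(year, 12, 25),                  # Christmas Day
    ]


@dataclass
class HolidayCalendar:
    """A set of holiday dates and their mapping onto a weekly grid.

    Parameters
    ----------
    dates:
        All holiday dates covering the study span.
    profile:
        Free-text label of the calendar profile (e.g. ``"US"``).
    dilate:
        Number of neighbouring weeks on each side also flagged as holiday
        weeks (0 = only the week containing the date).
    """

    dates: list[dt.date] = field(default_factory=list)
    profile: str = "custom"
    dilate: int = 0

    @classmethod
    def us(cls, start_year: int, end_year: int, dilate: int = 0) -> "HolidayCalendar":
        """US profile: federal holidays plus Easter and Good Friday."""
        dates: list[dt.date] = []
        for year in range(start_year, end_year + 1):
            dates.extend(us_federal_holidays(year))
            dates.append(easter_date(year))
            dates.append(good_friday(year))
        return cls(dates=sorted(set(dates)), profile="US", dilate=dilate)

    @classmethod
    def from_yaml(cls, path) -> "HolidayCalendar":
        """Load a calendar from YAML: ``{profile: str, dilate: int, dates: [ISO...]}``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dates = [dt.date.fromisoformat(str(d)) for d in raw.get("dates", [])]
        return cls(dates=sorted(set(dates)), profile=raw.get("profile", "custom"),
                   dilate=int(raw.get("dilate", 0)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"profile": self.profile, "dilate": self.dilate,
                 "dates": [d.isoformat() for d in self.dates]}, fh)

    def week_indices(self, study_start: dt.date, n_weeks: int) -> set[int]:
        """Week indices on the grid anchored at ``study_start`` containing
        at least one holiday date (optionally dilated)."""
        return holiday_weeks(self.dates, study_start, n_weeks, self.dilate)


def holiday_weeks(dates: Iterable[dt.date], study_start: dt.date,
                  n_weeks: int, dilate: int = 0) -> set[int]:
    """Map holiday dates onto 0-based 7-day bins anchored at ``study_start``."""
    weeks: set[int] = set()
    for d in dates:
        w = (d - study_start).days // 7
        if 0 <= w < n_weeks:
            for k in range(-dilate, dilate + 1):
                if 0 <= w + k < n_weeks:
                    weeks.add(w + k)
    return weeks


def holiday_smooth(values: Sequence[float], holiday_idx: Iterable[int],
                   flank: int = 2) -> np.ndarray:
    """Replace each holiday-week value by the mean of the nearest ``flank``
    non-holiday, non-missing weeks on each side.

    Non-holiday weeks are returned unchanged, so the transform is idempotent.
    At series edges fewer flanking weeks may be available; missing values
    (NaN) are skipped when searching for flanking weeks.

    Parameters
    ----------
    values:
        Weekly DR values (NaN = missing week).
    holiday_idx:
        Indices (into ``values``) of holiday-containing weeks.
    flank:
        Number of clean weeks to average on each side (``m >= 1``).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    y = np.asarray(values, dtype=float).copy()
    n = y.size
    hset = {i for i in holiday_idx if 0 <= i < n}
    clean = [i for i in range(n) if i not in hset and np.isfinite(y[i])]
    if not clean:
        raise ValueError("series consists entirely of holiday/missing weeks")
    clean_arr = np.array(clean)
    for i in sorted(hset):
        pos = np.searchsorted(clean_arr, i)
        left = clean_arr[max(0, pos - flank):pos]
        right = clean_arr[pos:pos + flank]
        neighbours = np.concatenate([left, right])
        y[i] = float(np.mean(y[neighbours.astype(int)])) if neighbours.size else np.nan
    return y
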