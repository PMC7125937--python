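"""365-day (no-leap) calendar helpers.

The whole pipeline runs on a no-leap calendar: every year has 365 days and
February has 28, matching the convention of many climate-model archives.
Day-of-year (doy) is 1-based: January 1 is doy 1, December 31 is doy 365.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: doy on which each month starts (January -> 1, February -> 32, ...)
MONTH_STARTS = np.concatenate([[1], 1 + np.cumsum(MONTH_LENGTHS)[:-1]])

#: June 1 .. August 31 inclusive on the no-leap calendar
JJA_START, JJA_END = 152, 243

#: mid-July, the default peak of the Northern-Hemisphere seasonal cycle
MID_JULY_DOY = 196

_MONTH_OF_DOY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)


def month_of_doy(doy):
    """Month number (1-12) for each 1-based day-of-year."""
    doy = np.asarray(doy)
    if np.any((doy < 1) | (doy > DAYS_PER_YEAR)):
        raise ValueError("day-of-year must lie in 1..365 (no-leap calendar)")
    out = _MONTH_OF_DOY[doy - 1]
    return out if out.ndim else int(out)


def is_jja(doy):
    """Boolean mask: does each day-of-year fall in June-August?"""
    doy = np.asarray(doy)
    return (doy >= JJA_START) & (doy <= JJA_END)
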