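"""Seasonal feed calendars for the two nutritional environments.

Two scenarios are supported:

``HS``
    the non-limiting ("high & stable") environment: cows have ad libitum
    access to feed, so the daily dry-matter offer is the unconstrained
    sentinel (``numpy.inf``).
``MS``
    the limiting ("moderate & stable") environment: the daily dry-matter
    offer follows a deterministic seasonal curve with a yearly mean of
    12.2 kg DM/d and a range of 10-16.8 kg DM/d, mimicking seasonal grass
    availability on a pasture-based system.

The metabolizable-energy (ME) content of the diet is shared by both
scenarios and varies seasonally between 10.85 and 12.45 MJ/kg DM with a
yearly mean of 11.70 MJ/kg DM.

Day 1 of the calendar is defined as the first day of the calving season,
which anchors the herd calendar used by :mod:`lactsel.herd_model`.

The seasonal shape is a smooth power-of-cosine curve,

    f(d) = lo + (hi - lo) * ((1 + cos(2*pi*(d - peak)/365)) / 2) ** p,

which attains ``lo`` and ``hi`` exactly; the exponent ``p`` is solved
numerically (deterministically) so that the mean over the 365 sampled days
equals the target mean exactly.  A simple sum of two harmonics cannot
reproduce the required peak/trough asymmetry of the offer curve without
violating its target range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

UNCONSTRAINED = np.inf
"""Sentinel dry-matter offer meaning ad libitum access."""

SEASON_DAYS = 365

# Target statistics of the two seasonal drivers (kg DM/d and MJ/kg DM).
MS_OFFER_MIN, MS_OFFER_MAX, MS_OFFER_MEAN = 10.0, 16.8, 12.2
ME_MIN, ME_MAX, ME_MEAN = 10.85, 12.45, 11.70

SCENARIOS = ("HS", "MS")


class ConfigurationError(ValueError):
    """Raised for invalid scenario labels or calendar settings."""


def _power_cosine(day: np.ndarray, lo: float, hi: float, p: float,
                  peak_day: float) -> np.ndarray:
    x = 2.0 * np.pi * (day - peak_day) / SEASON_DAYS
    return lo + (hi - lo) * ((1.0 + np.cos(x)) / 2.0) ** p


def _solve_exponent(lo: float, hi: float, mean: float, peak_day: float) -> float:
    """Exponent of the power-cosine curve giving the exact discrete mean."""
    days = np.arange(1, SEASON_DAYS + 1, dtype=float)

    def gap(p: float) -> float:
        return float(_power_cosine(days, lo, hi, p, peak_day).mean()) - mean

    # mean decreases monotonically from hi (p=0) towards lo (p -> inf)
    return brentq(gap, 1e-6, 60.0, xtol=1e-13)


@dataclass
class FeedCalendar:
    """Daily dry-matter offer and dietary energy content.

    Attributes
    ----------
    scenario : str
        "HS" (ad libitum) or "MS" (seasonally limiting offer).
    day_index : ndarray of int
        Day since simulation start, 1-based.  Day 1 is the first day of
        the calving season.
    dm_offer : ndarray of float
        kg DM/d per cow; ``numpy.inf`` in the HS scenario.
    me_content : ndarray of float
        MJ of metabolizable energy per kg DM.
    """

    scenario: str
    day_index: np.ndarray
    dm_offer: np.ndarray
    me_content: np.ndarray
    offer_peak_day: float = field(default=300.0)

    @property
    def n_days(self) -> int:
        return self.day_index.size

    def offer(self, day: int) -> float:
        """Dry-matter offer on 1-based day ``day``."""
        return float(self.dm_offer[day - 1])

    def me(self, day: int) -> float:
        """ME content (MJ/kg DM) on 1-based day ``day``."""
        return float(self.me_content[day - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day_index,
                "dm_offer_kg": self.dm_offer,
                "me_mj_per_kg": self.me_content,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_feed_calendar(scenario: str, n_years: int, *,
                       offer_peak_day: float = 300.0,
                       me_peak_day: float = 100.0) -> FeedCalendar:
    """Build the daily feed calendar for a nutritional scenario.

    Parameters
    ----------
    scenario : {"HS", "MS"}
        Non-limiting (ad libitum offer) or limiting (seasonal offer).
    n_years : int
        Number of 365-day seasons to generate (the calendar is periodic).
    offer_peak_day, me_peak_day : float
        Day of the seasonal cycle on which the offer / ME content peaks,
        relative to the start of the calving season.  The phase is a free
        calibration knob (the seasonal alignment of feed supply with the
        calving season is production-system specific).
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    if n_years < 1:
        raise ConfigurationError("n_years must be >= 1")

    season = np.arange(1, SEASON_DAYS + 1, dtype=float)

    # ME content: trough slightly sharper than the peak, so the inverted
    # power-cosine (exact min/max, mean solved) is used.
    p_me = _solve_exponent(-ME_MAX, -ME_MIN, -ME_MEAN, me_peak_day + SEASON_DAYS / 2.0)
    me_season = -_power_cosine(season, -ME_MAX, -ME_MIN, p_me,
                               me_peak_day + SEASON_DAYS / 2.0)

    if scenario == "HS":
        offer_season = np.full(SEASON_DAYS, UNCONSTRAINED)
    else:
        p_offer = _solve_exponent(MS_OFFER_MIN, MS_OFFER_MAX, MS_OFFER_MEAN,
                                  offer_peak_day)
        offer_season = _power_cosine(season, MS_OFFER_MIN, MS_OFFER_MAX,
                                     p_offer, offer_peak_day)

    reps = int(n_years)
    day_index = np.arange(1, reps * SEASON_DAYS + 1)
    return FeedCalendar(
        scenario=scenario,
        day_index=day_index,
        dm_offer=np.tile(offer_season, reps),
        me_content=np.tile(me_season, reps),
        offer_peak_day=offer_peak_day,
    )
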