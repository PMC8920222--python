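"""Exposure bookkeeping: cumulative-dose arithmetic and isodose pairing.

Chronic irradiation experiments are described by a dose rate (mGy/h of
continuous gamma exposure) and a duration in weeks of culture.  The total
cumulative dose is the product of the two, with a week counted as exactly
168 hours.  Conditions that accumulated near-equal total doses through
different rate/duration combinations form *isodose pairs*, the unit of
comparison for the downstream omics stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

__all__ = [
    "ExposureCondition",
    "IsodosePair",
    "cumulative_dose",
    "printed_dose",
    "pair_isodose",
]

HOURS_PER_WEEK = 24 * 7

#: Default relative tolerance for calling two cumulative doses "equal".
DEFAULT_ISODOSE_TOLERANCE = 0.15


@dataclass(frozen=True)
class ExposureCondition:
    """One chronic-exposure arm: a dose rate applied for a number of weeks.

    Parameters
    ----------
    label : str
        Unique name of the condition (e.g. ``"1.4mGyh_10wk"``).
    dose_rate : float
        Dose rate in mGy per hour; 0 denotes the sham-irradiated control.
    duration : float
        Exposure time in weeks; must be positive.
    """

    label: str
    dose_rate: float
    duration: float

    def __post_init__(self) -> None:
        if self.dose_rate < 0:
            raise ValueError(f"dose_rate must be >= 0, got {self.dose_rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0 weeks, got {self.duration}")

    @property
    def dose(self) -> float:
        return cumulative_dose(self)


@dataclass(frozen=True)
class IsodosePair:
    """Two conditions whose cumulative doses agree within a relative gap."""

    condition_a: ExposureCondition
    condition_b: ExposureCondition
    dose_a: float
    dose_b: float
    relative_gap: float

    @property
    def mean_dose(self) -> float:
        return 0.5 * (self.dose_a + self.dose_b)


def cumulative_dose(condition: ExposureCondition) -> float:
    """Total cumulative dose in Gy: dose_rate [mGy/h] x 168 h/wk x weeks / 1000.

    The value is returned unrounded; use :func:`printed_dose` for the
    reporting precision.

    >>> cumulative_dose(ExposureCondition("x", 1.4, 1))
    0.2352
    """
    return condition.dose_rate * HOURS_PER_WEEK * condition.duration / 1000.0


def printed_dose(dose_gy: float) -> float:
    """Round a dose to reporting precision.

    Doses below 3 Gy are reported to two decimals, larger doses to one,
    rounding half away from zero (so 0.2352 -> 0.24, 2.0664 -> 2.07,
    4.0320 -> 4.0).  This mixed precision mirrors how chronic-exposure
    doses are conventionally tabulated: sub-Gy values need two decimals
    to stay distinguishable.
    """
    ndigits = 2 if dose_gy < 3 else 1
    scale = 10**ndigits
    # round-half-away-from-zero; banker's rounding would give 0.23 for 0.235
    return math.floor(abs(dose_gy) * scale + 0.5) / scale * (1 if dose_gy >= 0 else -1)


def pair_isodose(
    conditions: list[ExposureCondition],
    tolerance: float = DEFAULT_ISODOSE_TOLERANCE,
) -> list[IsodosePair]:
    """Find all unordered pairs of distinct conditions with near-equal doses.

    Parameters
    ----------
    conditions : list of ExposureCondition
        At least two conditions with unique labels.
    tolerance : float
        Maximal admissible relative gap ``|d_a - d_b| / max(d_a, d_b)``,
        in (0, 1).

    Returns
    -------
    list of IsodosePair
        Each qualifying pair once, with the lower-dose condition first,
        sorted by ascending mean dose.
    """
    if not conditions:
        raise ValueError("condition list is empty")
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to pair")
    if not (0 < tolerance < 1):
        raise ValueError(f"tolerance must be in (0, 1), got {tolerance}")
    labels = [c.label for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique")

    pairs: list[IsodosePair] = []
    for a, b in combinations(conditions, 2):
        da, db = cumulative_dose(a), cumulative_dose(b)
        hi = max(da, db)
        if hi == 0:
            continue  # two sham arms never form an isodose pair
        gap = abs(da - db) / hi
        if gap <= tolerance:
            if db < da:
                a, b, da, db = b, a, db, da
            pairs.append(IsodosePair(a, b, da, db, gap))
    pairs.sort(key=lambda p: p.mean_dose)
    return pairs
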