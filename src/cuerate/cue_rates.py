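"""Cue-rate estimation: corrected cue counts per whale per unit time.

The central quantity is

    r(t) = N_C(t) / (N_W(t) * P_SA * t_SA)

where N_C is the estimated number of cues produced in a sensor's search
area over a period, N_W the independently estimated number of whales
passing during that period, P_SA the proportion of those whales whose
paths cross the search area (from the visually observed offshore
distribution), and t_SA the mean time a whale spends inside it.  The
same relation inverted gives abundance from cue counts when a cue rate
is known.

This module also provides the visual-sighting summaries that feed the
rate: the offshore distribution of migrating pods, the proportion of
whales inside a range band, and the daily southbound proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import TransitTime

__all__ = [
    "SightingRecord",
    "OffshoreDistribution",
    "DirectionSummary",
    "DailyAbundance",
    "CueRateEstimate",
    "build_offshore_distribution",
    "proportion_in_interval",
    "southbound_proportion",
    "cue_rate",
]

MINUTES_PER_DAY = 1440.0
MINUTES_PER_HOUR = 60.0


class EmptyDistributionError(ValueError):
    """No qualifying sightings to build an offshore distribution from."""


class UndefinedRateError(ZeroDivisionError):
    """Cue-rate denominator is zero or effectively zero."""


@dataclass(frozen=True)
class SightingRecord:
    """One visual sighting of a whale pod."""

    time: pd.Timestamp
    bearing_deg: float
    range_m: float
    group_size: int
    direction: str  # "south" | "north" | "milling"
    beaufort: int
    visibility_code: int
    pod_id: int | None = None

    def __post_init__(self) -> None:
        if self.range_m <= 0:
            raise ValueError("sighting range must be positive")
        if self.group_size < 1:
            raise ValueError("group size must be at least 1")


@dataclass
class OffshoreDistribution:
    """Whale counts by offshore range: one (mean range, whales) pair per pod."""

    ranges_m: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.ranges_m = np.asarray(self.ranges_m, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.ranges_m.shape != self.weights.shape:
            raise ValueError("ranges and weights must align")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.ranges_m.size and self.weights.sum() <= 0:
            raise EmptyDistributionError("all weights are zero")

    @property
    def total_whales(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class DirectionSummary:
    """Per-day proportion of sighted whales not travelling south (c_N)."""

    day: int
    c_n: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_n <= 1.0:
            raise ValueError("c_N must be in [0, 1]")


@dataclass(frozen=True)
class DailyAbundance:
    """Externally modelled daily whale abundance with 95% credibility bounds."""

    day: int
    median_whales: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.median_whales <= self.ci_high:
            raise ValueError("require 0 <= ci_low <= median <= ci_high")


@dataclass(frozen=True)
class CueRateEstimate:
    """A cue rate with abundance-CI-propagated bounds.

    ``rate`` is in cues/whale/``unit`` where unit is "day" or "hour".
    The lower bound uses the abundance CI's upper end (more whales,
    fewer cues each) and vice versa.
    """

    period: int
    rate: float
    lower: float
    upper: float
    unit: str
    p_sa: float
    t_sa: TransitTime


def _qualifying(s: SightingRecord, max_beaufort: int, max_visibility: int) -> bool:
    return (
        s.direction == "south"
        and s.beaufort < max_beaufort
        and s.visibility_code < max_visibility
    )


def build_offshore_distribution(
    sightings: Sequence[SightingRecord],
    max_beaufort: int = 5,
    max_visibility: int = 5,
) -> OffshoreDistribution:
    """Offshore distribution of southbound pods from visual sightings.

    Each southbound pod sighted in Beaufort and visibility conditions
    strictly below the cutoffs contributes one point: its offshore range
    is the mean range over all of the pod's sightings, and its weight is
    the pod's last recorded group size.  Pods are keyed by ``pod_id``
    (sightings without one are treated as singleton pods).
    """
    groups: dict[object, list[SightingRecord]] = {}
    for i, s in enumerate(sightings):
        key = s.pod_id if s.pod_id is not None else ("anon", i)
        groups.setdefault(key, []).append(s)

    ranges, weights = [], []
    for recs in groups.values():
        recs = sorted(recs, key=lambda r: r.time)
        last = recs[-1]
        # pod direction/conditions are taken from the last recorded values
        if not _qualifying(last, max_beaufort, max_visibility):
            continue
        ranges.append(float(np.mean([r.range_m for r in recs])))
        weights.append(float(last.group_size))
    if not ranges:
        raise EmptyDistributionError("no qualifying southbound pods")
    return OffshoreDistribution(ranges_m=np.array(ranges), weights=np.array(weights))


def proportion_in_interval(
    dist: OffshoreDistribution, r_min: float, r_max: float
) -> float:
    """Whale-weighted fraction of the distribution with r_min < r <= r_max."""
    if r_min >= r_max:
        raise ValueError("require r_min < r_max")
    if dist.ranges_m.size == 0 or dist.total_whales <= 0:
        raise EmptyDistributionError("empty offshore distribution")
    inside = (dist.ranges_m > r_min) & (dist.ranges_m <= r_max)
    return float(dist.weights[inside].sum() / dist.total_whales)


def southbound_proportion(
    sightings: Sequence[SightingRecord], day: int
) -> DirectionSummary:
    """Group-size-weighted non-southbound proportion c_N for one day.

    Each pod counts once with its last recorded direction and group
    size; c_N = 1 - southbound whales / all whales.  Calls attributed to
    northbound or milling whales are removed from southbound cue counts
    by the (1 - c_N) factor of the call correction.
    """
    if not sightings:
        raise ValueError(f"no sightings on day {day}")
    groups: dict[object, SightingRecord] = {}
    for i, s in enumerate(sightings):
        key = s.pod_id if s.pod_id is not None else ("anon", i)
        prev = groups.get(key)
        if prev is None or s.time >= prev.time:
            groups[key] = s
    total = sum(s.group_size for s in groups.values())
    south = sum(s.group_size for s in groups.values() if s.direction == "south")
    return DirectionSummary(day=day, c_n=1.0 - south / total)


def _transit_in_unit(t_sa: TransitTime, unit: str) -> float:
    if unit == "day":
        return t_sa.value_days
    if unit == "hour":
        return t_sa.value_hours
    raise ValueError(f"unknown rate unit {unit!r}; use 'day' or 'hour'")


def cue_rate(
    n_c_corrected: float,
    abundance: DailyAbundance,
    p_sa: float,
    t_sa: TransitTime,
    unit: str = "day",
    min_denominator: float = 1e-9,
) -> CueRateEstimate:
    """Cues per whale per unit time from a corrected cue count.

    ``rate = N_C / (N_W * P_SA * t_SA)`` with the transit time expressed
    in the requested unit (days for calls, hours for blows by
    convention).  Bounds substitute the abundance credibility interval:
    ci_high gives the lower rate bound, ci_low the upper.  Rates whose
    denominator would vanish are refused rather than returned as
    near-infinities, since downstream abundance estimates diverge as the
    rate approaches zero.
    """
    if not 0.0 < p_sa <= 1.0:
        raise ValueError("P_SA must be in (0, 1]")
    if n_c_corrected < 0:
        raise ValueError("corrected cue count must be nonnegative")
    t = _transit_in_unit(t_sa, unit)
    if t <= 0:
        raise UndefinedRateError("transit time must be positive")

    def _rate(n_w: float) -> float:
        denom = n_w * p_sa * t
        if denom < min_denominator:
            raise UndefinedRateError(
                f"denominator {denom:g} below {min_denominator:g}: rate undefined"
            )
        return n_c_corrected / denom

    upper = (
        _rate(abundance.ci_low)
        if abundance.ci_low * p_sa * t >= min_denominator
        else float("inf")
    )
    return CueRateEstimate(
        period=abundance.day,
        rate=_rate(abundance.median_whales),
        lower=_rate(abundance.ci_high),
        upper=upper,
        unit=unit,
        p_sa=p_sa,
        t_sa=t_sa,
    )
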