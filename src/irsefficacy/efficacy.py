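"""Threshold-based residual-efficacy duration.

WHO quantifies residual efficacy as the number of months post-spray during
which mosquito mortality stays at or above a threshold (80% for effective IRS).
Slow-acting products show occasional sub-threshold "dip" months followed by
recovery; the duration reported here is the LAST grid month at or above the
threshold, with interior dips listed rather than truncating the duration. A
strict variant (duration ends at the first sub-threshold month) is available
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .correction import CorrectedSeries
from .errors import EmptySeriesError

#: WHO effectiveness threshold for IRS cone-bioassay mortality.
WHO_THRESHOLD = 0.80


def _round_pct(mortality: float) -> float:
    """Mortality as percent rounded to one decimal (reporting precision)."""
    return round(100.0 * mortality, 1)


@dataclass(frozen=True)
class EfficacyDuration:
    """Residual-efficacy duration for one corrected series.

    Attributes
    ----------
    threshold : float
        Mortality fraction defining efficacy (default 0.80).
    duration_months : float
        Last observed grid month with mortality at/above threshold; 0.0 if the
        threshold is never reached.
    dip_months : tuple of (month, mortality)
        Sub-threshold months earlier than ``duration_months``.
    censored : bool
        True when the final observed month is still at/above threshold, so the
        true duration extends beyond the observation window.
    """

    threshold: float
    duration_months: float
    dip_months: tuple[tuple[float, float], ...]
    censored: bool


def residual_duration(
    series: CorrectedSeries | Iterable[tuple[float, float]],
    threshold: float = WHO_THRESHOLD,
    *,
    rule: str = "last",
) -> EfficacyDuration:
    """Residual-efficacy duration of a corrected mortality series.

    Parameters
    ----------
    series : CorrectedSeries or iterable of (month, mortality) pairs
        Discarded points of a :class:`CorrectedSeries` are excluded; point
        order is irrelevant (sorted internally).
    threshold : float
        Mortality fraction in (0, 1]; the at-or-above comparison is made on
        mortality rounded to one decimal in percent, so 79.95% counts as 80%.
    rule : {"last", "strict"}
        "last": duration is the last month at/above threshold, tolerating
        interior dips (reported). "strict": duration ends at the month before
        the first sub-threshold month.

    Raises
    ------
    EmptySeriesError
        If the series has no usable points.
    """
    if rule not in ("last", "strict"):
        raise ValueError(f"unknown rule {rule!r}")
    if isinstance(series, CorrectedSeries):
        pts = [(p.visit_month, p.corrected_mortality) for p in series.active_points()]
    else:
        pts = [(float(m), float(x)) for m, x in series]
    if not pts:
        raise EmptySeriesError("empty mortality series")
    pts.sort()
    threshold_pct = round(100.0 * threshold, 1)
    above = [_round_pct(x) >= threshold_pct for _, x in pts]

    if rule == "strict":
        duration = 0.0
        for (month, _), ok in zip(pts, above):
            if not ok:
                break
            duration = month
        dips = ()
    else:
        duration = 0.0
        for (month, _), ok in zip(pts, above):
            if ok:
                duration = month
        dips = tuple(
            (month, x) for (month, x), ok in zip(pts, above)
            if not ok and month < duration
        )
    censored = duration > 0 and duration == pts[-1][0]
    return EfficacyDuration(threshold, duration, dips, censored)


def duration_table(series_list: Iterable[CorrectedSeries],
                   threshold: float = WHO_THRESHOLD, **kwargs) -> pd.DataFrame:
    """Duration report across strata: one row per corrected series."""
    rows = []
    for s in series_list:
        try:
            d = residual_duration(s, threshold, **kwargs)
        except EmptySeriesError:
            continue
        rows.append(dict(
            wall_type=s.wall_type,
            age_group=s.age_group,
            hour=s.hour,
            threshold=threshold,
            duration_months=d.duration_months,
            censored=d.censored,
            dips="; ".join(f"{m:.1f}:{_round_pct(x):.1f}%" for m, x in d.dip_months),
        ))
    return pd.DataFrame(rows)
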